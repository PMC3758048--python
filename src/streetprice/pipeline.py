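"""End-to-end pipeline: ingest → filter → estimate → cross-validate → potency.

``run_pipeline`` reads the three dialect CSVs, applies the per-source
credibility filters, and writes the run's artifact bundle:

* ``summary_table.csv``/``.json`` — per-(drug, source) geometric means (long form)
* ``price_table_wide.csv`` — per-drug rows with per-source n and mean (CI)
* ``correlations.json`` — pairwise Spearman agreement between sources
* ``difference_tests.json`` — per-drug Welch ANOVA across sources
* ``potency_table.csv``/``.json`` — predicted relative potency vs clinical factors
* ``scatter_pairs.csv`` — per-drug mean pairs behind each correlation
* ``filter_audit.json``, ``rejects.csv`` — traceability of every dropped row
* ``run_metadata.json`` — config hash, seed, library versions

All randomness (bootstrap resampling) is governed by the configured seed,
so a rerun with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .crossval import compare_drug_across_sources, cross_source_matrix
from .errors import ConfigurationError, DomainError
from .estimation import summarize
from .filtering import FilterConfig, apply_filters
from .ingestion import ExchangeRateTable, read_reports, write_reports
from .potency import EquianalgesicTable, format_ratio, predicted_relative_potency, CLINICAL_CAVEAT
from .synthetic import default_filter_configs


class PipelineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    crowdsourced_path: Optional[str] = None
    law_enforcement_path: Optional[str] = None
    marketplace_path: Optional[str] = None
    rates_path: Optional[str] = None
    equianalgesic_path: Optional[str] = None
    filters: Optional[dict[str, FilterConfig]] = None
    alpha: float = 0.05
    ci_method: str = "tdist"
    n_boot: int = 2000
    seed: int = 0
    outdir: str = "results"
    formats: tuple[str, ...] = ("csv", "json")

    def source_paths(self) -> dict[str, str]:
        paths = {
            "crowdsourced": self.crowdsourced_path,
            "law_enforcement": self.law_enforcement_path,
            "marketplace": self.marketplace_path,
        }
        return {k: v for k, v in paths.items() if v}


def config_from_yaml(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "filters" in raw and raw["filters"] is not None:
        raw["filters"] = {k: FilterConfig(**v) for k, v in raw["filters"].items()}
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    # hash only analysis-relevant settings, not where outputs land
    payload = json.dumps(
        config.model_dump(mode="json", exclude={"outdir"}), sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the full analysis; returns artifact name -> path."""
    if not 0 < config.alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    paths = config.source_paths()
    if not paths:
        raise ConfigurationError("at least one source path is required")
    for name, p in list(paths.items()) + (
        [("rates", config.rates_path)] if config.rates_path else []
    ):
        if not Path(p).exists():
            raise ConfigurationError(f"input file for {name} not found: {p}")

    rates = ExchangeRateTable.from_csv(config.rates_path) if config.rates_path else None
    filters = config.filters or default_filter_configs()

    kept_frames, rejects_frames, audits = [], [], {}
    for source, path in paths.items():
        reports, rejects = read_reports(path, source, rates=rates)
        if source not in filters:
            raise ConfigurationError(f"no filter config for source {source!r}")
        result = apply_filters(reports, filters[source])
        kept_frames.append(result.kept)
        rejects["source"] = source
        rejects_frames.append(rejects)
        audits[source] = {
            "n_input": result.n_input,
            "n_rejected_at_parse": len(rejects),
            "n_kept": len(result.kept),
            "removed_by_rule": result.removed_by_rule,
            "rule_order": list(result.rule_order),
        }

    kept = pd.concat(kept_frames, ignore_index=True)
    summaries = summarize(kept, alpha=config.alpha, method=config.ci_method, seed=config.seed)

    correlations = cross_source_matrix(summaries)

    diff_tests = []
    for drug in sorted(kept["drug"].dropna().unique()):
        try:
            res = compare_drug_across_sources(kept, drug)
        except DomainError:
            continue
        diff_tests.append(
            {
                "drug": drug,
                "test": "welch_anova_log_price",
                "statistic": res.statistic,
                "p_value": res.p_value,
                "df_between": res.df_between,
                "df_within": res.df_within,
            }
        )

    table = EquianalgesicTable.from_csv(config.equianalgesic_path) if config.equianalgesic_path \
        else EquianalgesicTable.default()
    crowd_summaries = summaries[summaries["source"] == "crowdsourced"]
    potency_estimates = []
    if "morphine" in set(crowd_summaries["drug"]):
        crowd_reports = kept[kept["source"] == "crowdsourced"]
        potency_estimates = predicted_relative_potency(
            crowd_summaries,
            table=table,
            raw_reports=crowd_reports,
            n_boot=config.n_boot,
            seed=config.seed,
        )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _write_json(name: str, payload) -> None:
        path = outdir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        artifacts[name] = str(path)

    summary_csv = outdir / "summary_table.csv"
    summaries.to_csv(summary_csv, index=False)
    artifacts["summary_table.csv"] = str(summary_csv)
    if "json" in config.formats:
        _write_json("summary_table.json", summaries.to_dict(orient="records"))

    rejects_all = pd.concat(rejects_frames, ignore_index=True)
    rejects_csv = outdir / "rejects.csv"
    rejects_all.to_csv(rejects_csv, index=False)
    artifacts["rejects.csv"] = str(rejects_csv)

    kept_csv = outdir / "reports_kept.csv"
    write_reports(kept, kept_csv)
    artifacts["reports_kept.csv"] = str(kept_csv)

    _write_json("filter_audit.json", audits)
    _write_json(
        "correlations.json",
        [
            {
                "pair": list(c.source_pair),
                "n_drugs": c.n_drugs,
                "rho": round(c.rho, 4),
                "p": c.p_value,
                "method": c.method,
            }
            for c in correlations
        ],
    )
    _write_json("difference_tests.json", diff_tests)

    scatter_rows = []
    for c in correlations:
        wide = summaries.pivot(index="drug", columns="source", values="gm_price_per_mg")
        a, b = c.source_pair
        for drug in c.drugs:
            scatter_rows.append(
                {"pair": f"{a}~{b}", "drug": drug, "x": wide.loc[drug, a], "y": wide.loc[drug, b]}
            )
    scatter_csv = outdir / "scatter_pairs.csv"
    pd.DataFrame(scatter_rows, columns=["pair", "drug", "x", "y"]).to_csv(scatter_csv, index=False)
    artifacts["scatter_pairs.csv"] = str(scatter_csv)

    render_tables(summaries, potency_estimates, outdir, config.formats)
    artifacts["price_table_wide.csv"] = str(outdir / "price_table_wide.csv")
    artifacts["potency_table.csv"] = str(outdir / "potency_table.csv")

    _write_json(
        "run_metadata.json",
        {
            "package": "streetprice",
            "version": __version__,
            "config_sha256": _config_hash(config),
            "seed": config.seed,
            "libraries": _library_versions(),
            "potency_caveat": CLINICAL_CAVEAT,
        },
    )
    return artifacts


def _library_versions() -> dict[str, str]:
    import numpy, scipy, pandas  # noqa: E401

    return {"numpy": numpy.__version__, "scipy": scipy.__version__, "pandas": pandas.__version__}


def _fmt_money(x: float) -> str:
    return f"{x:.2f}"


def render_tables(summaries: pd.DataFrame, potency_estimates, outdir, formats=("csv", "json")) -> None:
    """Write the wide per-drug price table and the potency table.

    Monetary cells print at 2 decimals as ``mean (low-high)``; potency
    ratios print at 1 decimal (2 below 0.5). Drugs lacking a clinical
    factor appear in the potency table without a comparison label.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    wide_path = outdir / "price_table_wide.csv"
    if summaries.empty:
        warnings.warn("no summaries to render; writing header-only tables")
        pd.DataFrame(columns=["drug"]).to_csv(wide_path, index=False)
    else:
        sources = list(dict.fromkeys(summaries["source"]))
        order = (
            summaries.sort_values("gm_price_per_mg", ascending=False)
            .drop_duplicates("drug")["drug"]
            .tolist()
        )
        rows = []
        cell = summaries.set_index(["drug", "source"])
        for drug in order:
            row = {"drug": drug}
            for source in sources:
                try:
                    rec = cell.loc[(drug, source)]
                except KeyError:
                    row[f"{source}_n"] = ""
                    row[f"{source}_mean_ci"] = ""
                    continue
                row[f"{source}_n"] = int(rec["n"])
                mean = _fmt_money(rec["gm_price_per_mg"])
                if rec["ci_defined"]:
                    row[f"{source}_mean_ci"] = f"{mean} ({_fmt_money(rec['ci_low'])}-{_fmt_money(rec['ci_high'])})"
                else:
                    row[f"{source}_mean_ci"] = mean
            rows.append(row)
        pd.DataFrame(rows).to_csv(wide_path, index=False)

    pot_path = outdir / "potency_table.csv"
    pot_rows = []
    for est in sorted(potency_estimates, key=lambda e: -e.predicted_potency):
        row = {
            "drug": est.drug,
            "n": est.n,
            "predicted_potency": format_ratio(est.predicted_potency),
            "ci": "",
            "clinical_factor": "" if est.clinical_factor is None else est.clinical_factor,
            "comparison": est.comparison or "",
        }
        if est.ci_low is not None:
            row["ci"] = f"({format_ratio(est.ci_low, True)}-{format_ratio(est.ci_high, True)})"
        pot_rows.append(row)
    pd.DataFrame(
        pot_rows, columns=["drug", "n", "predicted_potency", "ci", "clinical_factor", "comparison"]
    ).to_csv(pot_path, index=False)
    if "json" in formats:
        (outdir / "potency_table.json").write_text(
            json.dumps(
                {
                    "caveat": CLINICAL_CAVEAT,
                    "estimates": [
                        {
                            "drug": e.drug,
                            "predicted_potency": e.predicted_potency,
                            "ci_low": e.ci_low,
                            "ci_high": e.ci_high,
                            "clinical_factor": e.clinical_factor,
                            "comparison": e.comparison,
                        }
                        for e in potency_estimates
                    ],
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
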