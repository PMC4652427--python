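"""End-to-end pipeline: simulate or ingest a cohort, run every analysis,
write report tables and a run manifest.

Outputs (CSV, full precision) in the chosen directory:

* ``table1_demographics.csv`` — group demographics with homogeneity tests;
* ``table2_sensitivity.csv`` — effect-size chain per group and instrument;
* ``table3_rci.csv`` — reliable-change parameters and percent outside;
* ``table4_global_change.csv`` — logistic fits of stage increase;
* ``table5_correlations_year1.csv`` / ``table6_correlations_year2.csv``;
* ``manifest.json`` — seed, config hash, package version.

A "summary mode" (:func:`summary_table`) runs the effect-size and
sample-size machinery directly on published group-level summary
statistics, with no subject-level cohort at all.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .descriptives import correlation_tables, demographics_table
from .global_change import MultiplicityRule, global_change_table
from .power import TrialDesign, required_per_arm
from .rci import rci_table
from .reference import REFERENCE_ROWS, TRIAL_YEARS
from .sensitivity import sensitivity_from_summary, sensitivity_table
from .simulate import SyntheticCohortConfig, generate_cohort, reference_config

__all__ = ["PipelineConfig", "run_pipeline", "summary_table"]


@dataclass
class PipelineConfig:
    """What to run and where to put it.

    Exactly one of ``cohort_csv`` / ``synthetic`` selects the input; a
    seed is required (and used) only when simulating.
    """

    out_dir: str | Path
    cohort_csv: str | Path | None = None
    synthetic: SyntheticCohortConfig | None = None
    design_years: dict[str, float] | None = None
    multiplicity: MultiplicityRule = MultiplicityRule()

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one input source (cohort_csv or synthetic) required")


def _attach_sample_sizes(table: pd.DataFrame, years: dict[str, float]) -> pd.DataFrame:
    per_arm = []
    for _, row in table.iterrows():
        try:
            res = required_per_arm(
                row["mean_change"],
                row["sd_change"],
                TrialDesign(years=years.get(row["group"], 1.0)),
            )
            per_arm.append(res.per_arm_n)
        except ValueError:
            per_arm.append(pd.NA)
    out = table.copy()
    out["n_per_arm"] = per_arm
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every analysis stage and write the report bundle.

    Returns a mapping from table name to written path.  Deterministic:
    the same config (and seed, when simulating) yields byte-identical
    outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    years = config.design_years or TRIAL_YEARS

    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        write_cohort(cohort, out_dir / "cohort.csv")
    else:
        cohort = read_cohort(config.cohort_csv)

    written: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.10g")
        written[name] = path

    demo = demographics_table(cohort)
    tests = demo.attrs["tests"]
    demo = demo.assign(
        **{
            f"p_{k}": [v[1]] * len(demo)
            for k, v in tests.items()
        }
    )
    emit("table1_demographics", demo)

    emit("table2_sensitivity", _attach_sample_sizes(sensitivity_table(cohort), years))
    emit("table3_rci", rci_table(cohort))
    emit("table4_global_change", global_change_table(cohort, config.multiplicity))
    corr = correlation_tables(cohort)
    emit("table5_correlations_year1", corr[1].reset_index(names="instrument"))
    emit("table6_correlations_year2", corr[2].reset_index(names="instrument"))

    manifest = {
        "version": __version__,
        "seed": config.synthetic.seed if config.synthetic else None,
        "input": "synthetic" if config.synthetic else str(config.cohort_csv),
        "n_subjects": len(cohort),
        "tables": sorted(written),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    written["manifest"] = out_dir / "manifest.json"
    return written


def summary_table(rows=REFERENCE_ROWS, years: dict[str, float] | None = None) -> pd.DataFrame:
    """Effect sizes, d and per-arm n recomputed from published summary rows.

    Runs the full chain (ES from mean change and pooled SD, d from ES and
    reliability, per-arm n from mean change and change SD under the
    group's trial length) on group-level inputs only.  Rows flagged as
    internally inconsistent in the source keep their computed values but
    carry ``es_consistent=False``.
    """
    years = years or TRIAL_YEARS
    out = []
    for row in rows:
        es, d, band = sensitivity_from_summary(row.mean_change, row.pooled_sd, row.reliability)
        n_arm = required_per_arm(
            row.mean_change, row.sd_change, TrialDesign(years=years[row.group])
        ).per_arm_n
        out.append(
            {
                "group": row.group,
                "instrument": row.instrument,
                "mean_change": row.mean_change,
                "sd_change": row.sd_change,
                "pooled_sd": row.pooled_sd,
                "reliability": row.reliability,
                "es": es,
                "d": d,
                "band": band,
                "n_per_arm": n_arm,
                "es_consistent": row.es_consistent,
            }
        )
    return pd.DataFrame(out)
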