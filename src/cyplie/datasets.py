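"""Embedded CYP 1A2 reference tables and the statistics derived from them.

Four small tables ship with the package:

- ``table1`` — in-house vs literature IC50/dG_bind comparison for 12
  compounds; the spread of the ddG column estimates the experimental
  uncertainty of the affinity data.
- ``table2`` — predicted vs literature-reported inhibition mechanism for
  the 14 compounds with known mechanism.
- ``table3`` — observed/calculated binding free energies for the 35
  training-set compounds of the calibrated LIE model.
- ``table4`` — the same for the 22 external test-set compounds, plus the
  four reliability flags (A-D) and their total.

:func:`summary_statistics` recomputes every headline statistic from these
tables (uncertainty RMSD, training RMSE/r2, test SDEP, per-category SDEPs).
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

from .lie import regression_metrics
from .reliability import category_sdep

__all__ = ["load_fixture", "summary_statistics", "run_paper_report"]

_FIXTURES = ("table1", "table2", "table3", "table4")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the embedded reference tables by name."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {_FIXTURES}")
    with files("cyplie.data").joinpath(f"{name}.csv").open() as handle:
        return pd.read_csv(handle)


def summary_statistics() -> dict[str, float]:
    """Recompute the headline statistics from the embedded tables.

    Returns a flat mapping with the experimental-uncertainty RMSD and its
    extreme absolute deviations (table1), training RMSE and r2 (table3),
    test SDEP (table4) and per-reliability-category SDEPs (table4 flags).
    """
    t1 = load_fixture("table1")
    ddg = t1["ddg"].to_numpy(dtype=float)
    out: dict[str, float] = {
        "experimental_rmsd": float(np.sqrt(np.mean(ddg**2))),
        "experimental_min_abs_dev": float(np.min(np.abs(ddg))),
        "experimental_max_abs_dev": float(np.max(np.abs(ddg))),
    }

    t3 = load_fixture("table3")
    train = regression_metrics(t3["dg_obs"], t3["dg_obs"] - t3["residual"])
    out["training_rmse"] = train.rmse
    out["training_r2"] = train.r2
    out["training_max_abs_residual"] = train.max_abs_residual

    t4 = load_fixture("table4")
    test = regression_metrics(t4["dg_obs"], t4["dg_obs"] - t4["residual"])
    out["test_sdep"] = test.sdep
    out["test_max_abs_residual"] = test.max_abs_residual

    totals = t4[["flag_a", "flag_b", "flag_c", "flag_d"]].sum(axis=1)
    per_category = category_sdep(list(zip(totals, t4["residual"])))
    for category, (n, sdep) in per_category.items():
        out[f"category{category}_n"] = float(n)
        out[f"category{category}_sdep"] = sdep
    return out


# Printed reference values the recomputed statistics are reported beside.
_REFERENCE = {
    "experimental_rmsd": 3.3,
    "experimental_min_abs_dev": 0.4,
    "experimental_max_abs_dev": 6.9,
    "training_rmse": 4.1,
    "training_r2": 0.68,
    "test_sdep": 5.8,
    "category0_sdep": 4.6,
    "category1_sdep": 7.5,
    "category2_sdep": 6.4,
    "category3_sdep": 7.6,
}


def run_paper_report() -> pd.DataFrame:
    """Recomputed statistics side by side with their published values.

    Returns a DataFrame indexed by statistic with 'computed' and
    'reference' columns (reference is NaN for derived counts).
    """
    computed = summary_statistics()
    rows = [
        {
            "statistic": key,
            "computed": value,
            "reference": _REFERENCE.get(key, float("nan")),
        }
        for key, value in computed.items()
    ]
    return pd.DataFrame(rows).set_index("statistic")
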