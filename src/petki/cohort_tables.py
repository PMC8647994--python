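"""Bundled clinical reference tables and the method-comparison report.

The package ships the per-patient results of a published 24-patient
NSCLC dynamic FDG study: group 2 (n = 14) with standard-protocol Ki,
short-protocol Ki,s and SUV, and group 3 (n = 8) with short-protocol
Ki,s and SUV only.  ``method_comparison_report`` recomputes from these
tables the statistics the study reports and lays them next to the
published values at the published rounding.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .method_stats import passing_bablok, r_squared, spearman_rho

__all__ = [
    "load_group2",
    "load_group3",
    "PUBLISHED",
    "method_comparison_report",
]

#: statistics as printed in the source study (comparison column of the report)
PUBLISHED: dict[str, float] = {
    "mean_Ki": 0.0442,
    "mean_Ki_s": 0.0433,
    "spearman_Ki": 0.974,
    "r2_Ki": 0.9970,
    "pb_slope": 0.992,
    "pb_intercept": -0.0003,
    "mean_SUV_pooled": 11.57,
    "spearman_SUV": 0.923,
    "r2_SUV": 0.8746,
}

_ROUND = {
    "mean_Ki": 4, "mean_Ki_s": 4, "spearman_Ki": 3, "r2_Ki": 4,
    "pb_slope": 3, "pb_intercept": 4, "mean_SUV_pooled": 2,
    "spearman_SUV": 3, "r2_SUV": 4,
}


def _load(name: str) -> pd.DataFrame:
    pkg = resources.files("petki.data")
    raw = (pkg / name).read_bytes()
    checks = json.loads((pkg / "checksums.json").read_text())
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checks[name]:
        raise RuntimeError(
            f"fixture {name} failed its integrity check "
            f"(sha256 {digest[:12]}... != expected {checks[name][:12]}...)"
        )
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_group2() -> pd.DataFrame:
    """Group 2 (n = 14): Ki, Ki,s, SUV per patient."""
    return _load("table1_group2.csv")


def load_group3() -> pd.DataFrame:
    """Group 3 (n = 8): Ki,s and SUV per patient (short protocol only)."""
    return _load("table2_group3.csv")


@dataclass(frozen=True)
class TableReport:
    computed: dict[str, float]
    published: dict[str, float]
    pb_slope_ci: tuple[float, float]
    pb_intercept_ci: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, pub in self.published.items():
            comp = self.computed[key]
            rows.append(
                {
                    "statistic": key,
                    "computed": round(comp, _ROUND[key]),
                    "published": pub,
                    "computed_full": comp,
                }
            )
        return pd.DataFrame(rows)


def method_comparison_report() -> TableReport:
    """Recompute the study's summary statistics from the bundled tables."""
    g2 = load_group2()
    g3 = load_group3()
    ki = g2["Ki"].to_numpy()
    kis = g2["Ki_s"].to_numpy()
    suv = np.concatenate([g2["SUV"].to_numpy(), g3["SUV"].to_numpy()])
    kis_all = np.concatenate([kis, g3["Ki_s"].to_numpy()])

    pb = passing_bablok(ki, kis)
    computed = {
        "mean_Ki": float(ki.mean()),
        "mean_Ki_s": float(kis.mean()),
        "spearman_Ki": spearman_rho(ki, kis),
        "r2_Ki": r_squared(ki, kis),
        "pb_slope": pb.slope,
        "pb_intercept": pb.intercept,
        "mean_SUV_pooled": float(suv.mean()),
        "spearman_SUV": spearman_rho(suv, kis_all),
        "r2_SUV": r_squared(suv, kis_all),
    }
    return TableReport(
        computed=computed,
        published=dict(PUBLISHED),
        pb_slope_ci=pb.slope_ci,
        pb_intercept_ci=pb.intercept_ci,
    )
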