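"""Self-checks of the packaged reference table against its published summary.

Each check recomputes a published quantity from the packaged 20-model table
and compares it at the printed precision.  Checks that depend only on the
printed values (index additivity, target-point selection and averages,
group means, the retention threshold) must reproduce exactly; ordination
checks carry the +/-0.5-point band appropriate for 3-decimal inputs.
"""

from __future__ import annotations

import numpy as np

from .complexity_table import fixture_table1
from .ordination_ctp import dim1_ci_correlation, hcpc, ksp_retention, mfa, select_ctp

PUBLISHED_CTP_MEAN = {
    "C": 0.550, "P_t": 0.607, "D_t": 0.412, "R": 0.483,
    "H_t": 2.372, "J": 0.862, "CI": 5.286,
}
PUBLISHED_SELECTION = {"BIOM5", "BIOM6", "BIOM7", "PROD3", "PROD4"}


def run_validation() -> list[tuple[str, bool, str]]:
    """Return (check name, passed, detail) for every reference-table check."""
    table = fixture_table1()
    checks: list[tuple[str, bool, str]] = []

    ci_check = table.validate_ci(tolerance=0.002)
    checks.append(
        (
            "CI equals six-metric sum (printed rounding)",
            bool(ci_check["ok"].all()),
            f"max |CI - sum| = {ci_check['delta'].abs().max():.4f}",
        )
    )

    means = table.purpose_means()
    prot_ok = (
        abs(means.loc["protection", "CI"] - 2.858) <= 0.001
        and abs(means.loc["protection", "C"] - 0.692) <= 0.001
    )
    prod_ok = (
        abs(means.loc["production", "CI"] - 3.599) <= 0.001
        and abs(means.loc["production", "C"] - 0.435) <= 0.001
    )
    checks.append(
        (
            "purpose-group means (protection, production)",
            bool(prot_ok and prod_ok),
            f"protection CI {means.loc['protection', 'CI']:.3f}, "
            f"production CI {means.loc['production', 'CI']:.3f}",
        )
    )

    ctp = select_ctp(table, use_printed_distances=True)
    sel_ok = set(ctp.selected) == PUBLISHED_SELECTION
    thr_ok = abs(ctp.threshold - 1.112) <= 0.0005
    mean_ok = all(
        abs(ctp.ctp_mean[k] - v) <= 0.0005 for k, v in PUBLISHED_CTP_MEAN.items()
    )
    sd_ok = abs(ctp.ctp_sd["C"] - 0.232) <= 0.0005
    checks.append(
        (
            "target-point selection from printed distances",
            bool(sel_ok and thr_ok and mean_ok and sd_ok),
            f"threshold {ctp.threshold:.3f}, selected {sorted(ctp.selected)}",
        )
    )

    threshold, _ = ksp_retention(len(table), 6)
    checks.append(
        (
            "retention threshold (n=20, p=6)",
            bool(abs(threshold - 2.03) <= 0.005),
            f"threshold {threshold:.2f}",
        )
    )

    result = mfa(table)
    dim1_ok = abs(result.inertia_pct[0] - 43.21) <= 0.5
    checks.append(
        (
            "first-dimension inertia (43.21% +/- 0.5)",
            bool(dim1_ok),
            f"Dim.1 {result.inertia_pct[0]:.2f}%, Dim.2 {result.inertia_pct[1]:.2f}%",
        )
    )

    r, _ = dim1_ci_correlation(result, table)
    checks.append(
        ("Dim.1 vs CI correlation (0.92 at 2 dp)", bool(round(r, 2) == 0.92), f"r = {r:.4f}")
    )

    clusters = hcpc(result, k=3)
    biom = {m for m in table.model_ids if m.startswith("BIOM")}
    biom_clusters = {clusters.assignments[m] for m in biom}
    prod_cluster = {clusters.assignments[m] for m in table.model_ids if m.startswith("PROD")}
    prot4_ok = (
        len(prod_cluster) == 1
        and clusters.assignments["PROT4"] in prod_cluster
    )
    checks.append(
        (
            "3-cluster structure (bio-mimicry together, PROT4 with production)",
            bool(len(biom_clusters) == 1 and prot4_ok),
            f"assignments {clusters.assignments.to_dict()}",
        )
    )
    return checks
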