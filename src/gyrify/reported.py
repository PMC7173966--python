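"""Published group summaries used as worked-example inputs.

The study this package is built around reports only group-level summary
statistics (mean ± SD or SEM, n animals) with two-tailed Student's
t-test p-values.  Those printed summaries are the package's reference
dataset: :func:`gyrify.stats.students_t_from_summary` re-derives the
p-values from them, which both exercises the statistics module and
documents exactly which printed comparisons are reproducible from the
printed numbers alone.

``reproduces_printed`` records whether the pooled-variance two-tailed t
on the printed summaries rounds to the printed p at its printed
precision.  Comparisons where it does not (typically within-animal
contrasts, where the published test was presumably paired on per-animal
values that were not released, or values affected by rounding of the
printed mean/SD) are flagged False and are reported at their computed
value rather than guessed at.

Abbreviations in labels: ``cnr`` = EP/contralateral cell-number ratio;
``pct`` = subtype percentage among OSVZ progenitors; ``r2/r3/r5`` =
prospective sulcal (#2) and gyral (#3, #5) regions along the
anteroposterior axis; ``shh`` / ``hhip`` = Shh-N overexpression and
secreted Hhip (Shh-signalling inhibition) electroporation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

from gyrify.stats import GroupSummary


@dataclass(frozen=True)
class ReportedComparison:
    label: str
    metric: str
    group1: str
    g1: GroupSummary
    group2: str
    g2: GroupSummary
    printed_p: str
    reproduces_printed: bool


def _c(label, metric, name1, m1, d1, n1, name2, m2, d2, n2, printed_p, reproduces, kind="SD"):
    return ReportedComparison(
        label=label,
        metric=metric,
        group1=name1,
        g1=GroupSummary(m1, d1, kind, n1),
        group2=name2,
        g2=GroupSummary(m2, d2, kind, n2),
        printed_p=printed_p,
        reproduces_printed=reproduces,
    )


REPORTED_COMPARISONS: tuple[ReportedComparison, ...] = (
    # --- regional accumulation of progenitor subtypes (gyral #3,#5 vs sulcal #2)
    _c("ratio32_hopxpos_vs_all", "region #3/#2 count ratio", "HOPX+ oRG", 9.8, 4.4, 3, "all progenitors", 1.4, 0.2, 3, "0.03", True),
    _c("ratio32_hopxpos_vs_pax6", "region #3/#2 count ratio", "HOPX+ oRG", 9.8, 4.4, 3, "Pax6+", 1.3, 0.2, 3, "0.03", True),
    _c("ratio32_hopxneg_vs_all", "region #3/#2 count ratio", "HOPX- oRG", 0.5, 0.1, 3, "all progenitors", 1.4, 0.2, 3, "0.003", False),
    _c("ratio32_ip_vs_all", "region #3/#2 count ratio", "IP", 1.7, 0.5, 3, "all progenitors", 1.4, 0.2, 3, "0.29", False),
    _c("ratio52_hopxpos_vs_all", "region #5/#2 count ratio", "HOPX+ oRG", 19.9, 7.6, 3, "all progenitors", 1.5, 0.2, 3, "0.01", True),
    _c("ratio52_hopxneg_vs_all", "region #5/#2 count ratio", "HOPX- oRG", 0.34, 0.02, 3, "all progenitors", 1.5, 0.2, 3, "0.0005", False),
    _c("pct_hopxpos_r3_vs_r2", "% HOPX+ oRG of progenitors", "region #3", 34.6, 2.7, 3, "region #2", 6.1, 2.9, 3, "0.0002", True),
    _c("pct_hopxpos_r5_vs_r2", "% HOPX+ oRG of progenitors", "region #5", 34.5, 1.6, 3, "region #2", 3.2, 1.7, 3, "0.00002", True),
    _c("pct_hopxneg_r3_vs_r2", "% HOPX- oRG of progenitors", "region #3", 16.8, 5.7, 3, "region #2", 49.4, 12.5, 3, "0.01", True),
    _c("pct_hopxneg_r5_vs_r2", "% HOPX- oRG of progenitors", "region #5", 12.1, 1.8, 3, "region #2", 52.3, 3.8, 3, "0.00009", False),
    _c("pct_ip_r3_vs_r2", "% IP of progenitors", "region #3", 48.6, 3.3, 3, "region #2", 44.4, 10.4, 3, "0.31", False),
    _c("pct_ip_r5_vs_r2", "% IP of progenitors", "region #5", 53.4, 0.1, 3, "region #2", 44.5, 5.4, 3, "0.04", False),
    # --- proliferation and self-renewal of oRG subtypes
    _c("ki67_hopxpos_vs_neg", "% co-expressing Ki-67", "HOPX+ oRG", 30.3, 4.1, 3, "HOPX- oRG", 32.3, 4.6, 3, "0.34", False),
    _c("edu_hopxpos_vs_neg", "% co-labelled with EdU", "HOPX+ oRG", 22.2, 5.5, 3, "HOPX- oRG", 12.4, 1.8, 3, "0.04", True),
    _c("ki67edu_hopxpos_vs_neg", "% co-labelled Ki-67∧EdU", "HOPX+ oRG", 7.8, 0.6, 3, "HOPX- oRG", 2.8, 2.0, 3, "0.01", True),
    # --- Shh inhibition (secreted Hhip): self-renewal and proliferation
    _c("edu_hopxpos_ctrl_vs_hhip", "% HOPX+ oRG with EdU", "control", 23.6, 4.8, 3, "Hhip", 14.2, 1.2, 3, "0.03", True),
    _c("edu_ip_ctrl_vs_hhip", "% IP with EdU", "control", 32.7, 7.9, 3, "Hhip", 26.7, 2.0, 3, "0.17", False),
    _c("edu_hopxneg_ctrl_vs_hhip", "% HOPX- oRG with EdU", "control", 11.4, 3.8, 3, "Hhip", 12.6, 1.7, 3, "0.35", False),
    _c("ki67_hopxpos_ctrl_vs_hhip", "% HOPX+ with Ki-67", "control", 28.7, 2.0, 3, "Hhip", 29.5, 0.7, 3, "0.30", False),
    _c("ki67_ip_ctrl_vs_hhip", "% IP with Ki-67", "control", 36.4, 2.8, 3, "Hhip", 35.1, 3.9, 3, "0.35", False),
    _c("ki67_hopxneg_ctrl_vs_hhip", "% HOPX- with Ki-67", "control", 28.8, 2.7, 3, "Hhip", 25.2, 3.5, 3, "0.15", False),
    # --- Shh activation (Shh-N): cell-number ratios and proportions
    _c("cnr_hopxpos_osvz_shh", "HOPX+ cell-number ratio, OSVZ", "control", 1.00, 0.12, 3, "Shh-N", 2.38, 0.70, 3, "0.03", True),
    _c("cnr_hopxpos_isvz_shh", "HOPX+ cell-number ratio, ISVZ", "control", 1.05, 0.13, 3, "Shh-N", 1.71, 0.08, 3, "0.002", True),
    _c("cnr_ip_osvz_shh", "IP cell-number ratio, OSVZ", "control", 1.00, 0.24, 3, "Shh-N", 1.31, 0.22, 3, "0.13", False),
    _c("cnr_ip_isvz_shh", "IP cell-number ratio, ISVZ", "control", 1.17, 0.17, 3, "Shh-N", 1.31, 0.27, 3, "0.29", False),
    _c("cnr_hopxneg_osvz_shh", "HOPX- oRG cell-number ratio, OSVZ", "control", 1.06, 0.21, 3, "Shh-N", 1.40, 0.21, 3, "0.09", False),
    _c("cnr_hopxneg_isvz_shh", "HOPX- oRG cell-number ratio, ISVZ", "control", 1.09, 0.16, 3, "Shh-N", 1.31, 0.11, 3, "0.09", False),
    _c("pct_hopxpos_ctrl_vs_shh", "% HOPX+ oRG of progenitors", "control", 38.3, 1.3, 3, "Shh-N", 50.2, 2.4, 3, "0.002", True),
    _c("pct_hopxneg_ctrl_vs_shh", "% HOPX- oRG of progenitors", "control", 14.2, 3.7, 3, "Shh-N", 16.9, 5.6, 3, "0.30", False),
    _c("pct_ip_ctrl_vs_shh", "% IP of progenitors", "control", 47.5, 4.7, 3, "Shh-N", 33.0, 3.9, 3, "0.01", True),
    # --- Shh inhibition: cell-number ratios, proportions, apoptosis, mRNA
    _c("cnr_hopxpos_osvz_hhip", "HOPX+ cell-number ratio, OSVZ", "control", 1.02, 0.07, 3, "Hhip", 0.46, 0.04, 3, "0.0003", True),
    _c("cnr_hopxpos_isvz_hhip", "HOPX+ cell-number ratio, ISVZ", "control", 1.03, 0.12, 3, "Hhip", 0.55, 0.04, 3, "0.003", True),
    _c("pct_hopxpos_ctrl_vs_hhip", "% HOPX+ oRG of progenitors", "control", 40.8, 2.3, 3, "Hhip", 14.5, 6.7, 3, "0.003", True),
    _c("pct_hopxneg_ctrl_vs_hhip", "% HOPX- oRG of progenitors", "control", 14.6, 1.9, 3, "Hhip", 25.1, 3.3, 3, "0.009", True),
    _c("pct_ip_ctrl_vs_hhip", "% IP of progenitors", "control", 44.6, 1.5, 3, "Hhip", 60.4, 9.4, 3, "0.039", False),
    _c("cc3_osvz_hhip", "cleaved-caspase-3 cell-number ratio, OSVZ", "control", 1.12, 0.28, 3, "Hhip", 0.57, 0.49, 3, "0.12", False),
    _c("cc3_isvz_hhip", "cleaved-caspase-3 cell-number ratio, ISVZ", "control", 0.97, 0.58, 3, "Hhip", 0.50, 0.41, 3, "0.20", False),
    _c("hopxmrna_ctrl_vs_shh", "% HOPX- oRG with HOPX mRNA", "control", 0.9, 1.2, 3, "Shh-N", 1.1, 1.6, 3, "0.43", False),
    _c("hopxmrna_ctrl_vs_hhip", "% HOPX- oRG with HOPX mRNA", "control", 0.6, 0.9, 3, "Hhip", 0.5, 0.7, 3, "0.45", False),
    # --- fold morphometry ratios (mean ± SEM)
    _c("local_gn_ratio_shh", "local GN ratio", "control", 0.97, 0.05, 3, "Shh-N", 1.42, 0.06, 4, "0.003", True, kind="SEM"),
    _c("local_sd_ratio_hhip", "local SD ratio", "control", 1.03, 0.11, 3, "Hhip", 0.45, 0.03, 3, "0.006", False, kind="SEM"),
    _c("local_gs_ratio_hhip", "local GS ratio", "control", 0.86, 0.08, 3, "Hhip", 0.57, 0.06, 3, "0.038", False, kind="SEM"),
    _c("local_gn_ratio_hhip", "local GN ratio", "control", 1.06, 0.05, 3, "Hhip", 1.00, 0.00, 3, "0.19", False, kind="SEM"),
    # --- laminar thickness ratios (mean ± SD)
    _c("thick_l23_shh", "layer 2/3 thickness ratio", "control", 1.07, 0.16, 3, "Shh-N", 2.24, 0.27, 3, "0.003", True),
    _c("thick_l4_shh", "layer 4 thickness ratio", "control", 0.99, 0.15, 3, "Shh-N", 0.96, 0.09, 3, "0.42", False),
    _c("thick_l5_shh", "layer 5 thickness ratio", "control", 0.95, 0.05, 3, "Shh-N", 1.19, 0.09, 3, "0.01", False),
    _c("thick_l6_shh", "layer 6 thickness ratio", "control", 0.95, 0.04, 3, "Shh-N", 1.07, 0.15, 3, "0.17", False),
    _c("upper_lower_shh", "layer 2/3 : 4-6 thickness ratio", "control", 1.04, 0.23, 3, "Shh-N", 2.10, 0.42, 3, "0.02", True),
    _c("thick_l23_hhip", "layer 2/3 thickness ratio", "control", 0.92, 0.06, 3, "Hhip", 0.72, 0.06, 3, "0.02", True),
    _c("thick_l4_hhip", "layer 4 thickness ratio", "control", 0.90, 0.20, 3, "Hhip", 0.97, 0.12, 3, "0.34", False),
    _c("thick_l5_hhip", "layer 5 thickness ratio", "control", 1.01, 0.11, 3, "Hhip", 1.00, 0.10, 3, "0.47", False),
    _c("thick_l6_hhip", "layer 6 thickness ratio", "control", 1.05, 0.12, 3, "Hhip", 0.96, 0.10, 3, "0.22", False),
    _c("upper_lower_hhip", "layer 2/3 : 4-6 thickness ratio", "control", 0.96, 0.03, 3, "Hhip", 0.76, 0.10, 3, "0.03", True),
    # --- Shh pathway readouts, ferret vs mouse
    _c("gli1_area_ferret_vs_mouse", "% GLI1-positive area, germinal zone", "ferret", 8.89, 1.64, 3, "mouse", 3.69, 0.65, 3, "0.007", True),
    _c("gli1_rtpcr_ferret_vs_mouse", "relative GLI1 expression (RT-PCR)", "ferret", 0.58, 0.16, 3, "mouse", 0.30, 0.08, 3, "0.048", False),
    _c("shh_blot_ferret_vs_mouse", "Shh immunoblot, cortex/cerebellum", "ferret", 0.32, 0.05, 3, "mouse", 0.10, 0.01, 3, "0.002", True),
    _c("gli1_intensity_ferret_vs_mouse", "GLI1 intensity per HOPX+ cell", "ferret", 0.39, 0.06, 3, "mouse", 0.18, 0.05, 3, "0.04", False, kind="SEM"),
)

#: subtype proportion triples (% HOPX+ oRG, % HOPX- oRG, % IP) printed for
#: single conditions; each triple sums to ~100 and serves as a sanity check.
REPORTED_PROPORTION_TRIPLES: dict[str, tuple[float, float, float]] = {
    "region3": (34.6, 16.8, 48.6),
    "region2": (6.1, 49.4, 44.4),
    "shh_control": (38.3, 14.2, 47.5),
    "shh_n": (50.2, 16.9, 33.0),
    "hhip_control": (40.8, 14.6, 44.6),
    "hhip": (14.5, 25.1, 60.4),
}


def get_comparison(label: str) -> ReportedComparison:
    for comp in REPORTED_COMPARISONS:
        if comp.label == label:
            return comp
    raise KeyError(f"unknown comparison {label!r}")


def reproducible_comparisons() -> tuple[ReportedComparison, ...]:
    """Comparisons whose printed p is recovered by the default pooled test."""
    return tuple(c for c in REPORTED_COMPARISONS if c.reproduces_printed)
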