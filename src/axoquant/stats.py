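"""Well-level aggregation and the treatment-comparison statistics.

The statistical unit is the embryo: multiple explants from one embryo are
plated in one well per treatment (and possibly repeated wells), their radial
profiles are averaged to a well mean, and repeated wells of the same
embryo x treatment are averaged to one subject record.  Treatments are then
compared with a two-factor mixed-design ("split-plot") ANOVA — treatment as
the between-subject factor, coarse radial distance bin as the repeated
within-subject factor — followed by Dunnett's many-to-one comparison of each
treatment against a designated control within each distance bin.

The mixed-ANOVA decomposition implemented here is the textbook one: with
subject s in group g over B bins,

    F_treatment = MS_treatment / MS_subjects-within-groups,
    df = (g - 1, N - g),

and within-subject effects (distance, treatment x distance) tested against
the subject x distance residual.  Sphericity is not corrected by default; a
Greenhouse-Geisser epsilon correction of the within-subject tests is
available via ``gg=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profile import DEFAULT_COARSE_WIDTH_UM, RadialProfile

__all__ = ["ExperimentTable", "AnovaResult", "well_means", "rm_anova_dunnett"]

MIN_EMBRYOS_PER_TREATMENT = 3

WELL_MEAN = "WELL_MEAN"

_KEYS = ["embryo_id", "treatment", "rep"]


@dataclass
class ExperimentTable:
    """Tidy long table of explant and well-mean densities.

    ``data`` columns: embryo_id, treatment, rep, explant_id, bin_start_um,
    bin_end_um, density, is_well_mean.  Rows with ``is_well_mean`` carry
    ``explant_id == "WELL_MEAN"`` and hold, per well and nonempty bin, the
    arithmetic mean of that well's explant densities.
    """

    data: pd.DataFrame
    bin_width_um: float
    control_treatment: str | None = None

    def explant_rows(self) -> pd.DataFrame:
        return self.data[~self.data["is_well_mean"]]

    def well_mean_rows(self) -> pd.DataFrame:
        return self.data[self.data["is_well_mean"]]


def _profile_frame(profiles: list[RadialProfile]) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(profiles):
        meta = p.meta
        if meta is None:
            raise ValueError(f"profile {i} has no metadata; cannot aggregate")
        keep = p.bin_pixel_count > 0
        rows.append(pd.DataFrame({
            "embryo_id": meta.embryo_id,
            "treatment": meta.treatment,
            "rep": meta.rep,
            "explant_id": meta.explant_id,
            "bin_start_um": p.bin_edges_um[:-1][keep],
            "bin_end_um": p.bin_edges_um[1:][keep],
            "density": p.density[keep],
        }))
    return pd.concat(rows, ignore_index=True)


def well_means(profiles: list[RadialProfile], control_treatment: str | None = None) -> ExperimentTable:
    """Build the experiment table with per-well mean rows appended.

    All profiles must share bin geometry (width and scale).  The well mean in
    a bin is the unweighted mean over the explants of that well that have the
    bin; explants whose image does not reach a bin are excluded pairwise
    rather than treated as zero.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    widths = {p.bin_width_um for p in profiles}
    scales = {p.pixel_scale_um for p in profiles}
    if len(widths) > 1 or len(scales) > 1:
        raise ValueError(
            f"profiles have inconsistent bin geometry: widths {sorted(widths)}, scales {sorted(scales)}"
        )
    explants = _profile_frame(profiles)
    explants["is_well_mean"] = False
    means = (
        explants.groupby(_KEYS + ["bin_start_um", "bin_end_um"], as_index=False)["density"]
        .mean()
    )
    means["explant_id"] = WELL_MEAN
    means["is_well_mean"] = True
    data = pd.concat([explants, means], ignore_index=True)
    data = data.sort_values(_KEYS + ["is_well_mean", "explant_id", "bin_start_um"], ignore_index=True)
    return ExperimentTable(data=data, bin_width_um=widths.pop(), control_treatment=control_treatment)


@dataclass
class AnovaResult:
    """Mixed-design ANOVA summary plus per-bin Dunnett comparisons."""

    F_treatment: float
    df_num: int
    df_den: int
    p_treatment: float
    anova_table: pd.DataFrame
    dunnett: pd.DataFrame
    control_treatment: str
    coarse_width_um: float
    gg_epsilon: float | None = None

    def summary(self) -> str:
        lines = [
            "Two-factor mixed ANOVA (between: treatment; within: distance bin)",
            f"  treatment: F({self.df_num}, {self.df_den}) = {self.F_treatment:.4g}, "
            f"p = {self.p_treatment:.4g}",
        ]
        if self.gg_epsilon is not None:
            lines.append(f"  Greenhouse-Geisser epsilon (within tests): {self.gg_epsilon:.4g}")
        lines.append(f"Dunnett vs control '{self.control_treatment}', per {self.coarse_width_um:g} um bin:")
        for _, r in self.dunnett.iterrows():
            lines.append(
                f"  [{r.bin_start_um:g}-{r.bin_end_um:g} um] {r.treatment}: "
                f"diff = {r.mean_diff:+.4g}, p_adj = {r.p_adjusted:.4g}"
            )
        return "\n".join(lines)


def _coarse_subject_table(table: ExperimentTable, coarse_width_um: float) -> pd.DataFrame:
    """Collapse well means to one coarse-binned record per embryo x treatment."""
    wm = table.well_mean_rows().copy()
    if wm.empty:
        raise ValueError("experiment table has no well-mean rows")
    ratio = coarse_width_um / table.bin_width_um
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"coarse_width_um ({coarse_width_um}) must be a positive multiple "
            f"of the table bin width ({table.bin_width_um})"
        )
    wm["coarse_bin"] = np.floor(wm["bin_start_um"] / coarse_width_um + 1e-9).astype(int)
    # mean over fine bins within the coarse bin, then over repetition wells
    per_well = wm.groupby(_KEYS + ["coarse_bin"], as_index=False)["density"].mean()
    per_subject = per_well.groupby(["embryo_id", "treatment", "coarse_bin"], as_index=False)["density"].mean()
    return per_subject


def _balance(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Drop coarse bins beyond the shortest common maximum; reject holes."""
    per_subject = per_subject.copy()
    per_subject["subject"] = per_subject["embryo_id"] + "|" + per_subject["treatment"]
    common_max = int(per_subject.groupby("subject")["coarse_bin"].max().min())
    trimmed = per_subject[per_subject["coarse_bin"] <= common_max]
    expected = set(range(common_max + 1))
    bad = [
        subj for subj, grp in trimmed.groupby("subject")
        if set(grp["coarse_bin"]) != expected
    ]
    if bad:
        raise ValueError(
            "unbalanced distance bins within the common range for subjects "
            f"(embryo|treatment): {sorted(bad)}"
        )
    return trimmed


def _mixed_anova(Y: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Split-plot ANOVA table for subjects x bins matrix ``Y``.

    ``groups[s]`` is the between-factor level of subject (row) s.  Sums of
    squares follow the standard balanced-design decomposition; group sizes may
    differ (weighted cell means), but every subject must supply every bin.
    """
    n_subj, n_bins = Y.shape
    levels = np.unique(groups)
    g = levels.size
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    bin_means = Y.mean(axis=0)
    group_means = np.array([Y[groups == lv].mean() for lv in levels])
    cell_means = np.vstack([Y[groups == lv].mean(axis=0) for lv in levels])
    n_per = np.array([(groups == lv).sum() for lv in levels])

    ss_treat = n_bins * float(np.sum(n_per * (group_means - grand) ** 2))
    group_mean_of = group_means[np.searchsorted(levels, groups)]
    ss_subj = n_bins * float(np.sum((subj_means - group_mean_of) ** 2))
    ss_bin = n_subj * float(np.sum((bin_means - grand) ** 2))
    ss_inter = float(np.sum(n_per[:, None] * (cell_means - group_means[:, None] - bin_means[None, :] + grand) ** 2))
    cell_of = cell_means[np.searchsorted(levels, groups)]
    resid = Y - cell_of - subj_means[:, None] + group_mean_of[:, None]
    ss_err = float(np.sum(resid ** 2))

    df = {
        "treatment": g - 1,
        "subjects_within_groups": n_subj - g,
        "distance": n_bins - 1,
        "treatment_x_distance": (g - 1) * (n_bins - 1),
        "residual": (n_subj - g) * (n_bins - 1),
    }
    ss = {
        "treatment": ss_treat,
        "subjects_within_groups": ss_subj,
        "distance": ss_bin,
        "treatment_x_distance": ss_inter,
        "residual": ss_err,
    }
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in ss}
    rows = []
    for effect, err in [
        ("treatment", "subjects_within_groups"),
        ("distance", "residual"),
        ("treatment_x_distance", "residual"),
    ]:
        F = ms[effect] / ms[err] if ms[err] > 0 else np.nan
        p = float(sps.f.sf(F, df[effect], df[err])) if np.isfinite(F) else np.nan
        rows.append((effect, ss[effect], df[effect], ms[effect], F, df[err], p))
    for err in ("subjects_within_groups", "residual"):
        rows.append((err, ss[err], df[err], ms[err], np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["effect", "SS", "df", "MS", "F", "df_error", "p"])


def _gg_epsilon(Y: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    levels = np.unique(groups)
    parts = [Y[groups == lv] - Y[groups == lv].mean(axis=0) for lv in levels]
    resid = np.vstack(parts)
    S = resid.T @ resid / max(resid.shape[0] - levels.size, 1)
    b = S.shape[0]
    # double-centre the covariance matrix
    row = S.mean(axis=0)
    Sc = S - row[None, :] - row[:, None] + S.mean()
    num = np.trace(Sc) ** 2
    den = (b - 1) * float(np.sum(Sc ** 2))
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (b - 1))))


def rm_anova_dunnett(
    table: ExperimentTable,
    coarse_width_um: float = DEFAULT_COARSE_WIDTH_UM,
    control_treatment: str | None = None,
    *,
    gg: bool = False,
) -> AnovaResult:
    """Two-factor mixed ANOVA plus Dunnett's per-bin comparison vs control.

    Well means are coarse-binned (unweighted mean of fine-bin densities),
    repetition wells of the same embryo x treatment are averaged to one
    subject record, and bins beyond the shortest common maximum distance are
    dropped so the repeated-measures design is balanced.  Requires at least
    two treatments and at least three embryos per treatment.

    Dunnett's test is run separately within each coarse bin, comparing every
    non-control treatment against ``control_treatment`` at that bin; the
    family of contrasts is the set of treatment-vs-control comparisons within
    the bin.  Unadjusted two-sided p-values from the same pooled-variance t
    statistics are reported alongside for reference.
    """
    control = control_treatment or table.control_treatment
    if control is None:
        raise ValueError("control_treatment must be given (here or on the table)")
    per_subject = _balance(_coarse_subject_table(table, coarse_width_um))

    treatments = sorted(per_subject["treatment"].unique())
    if control not in treatments:
        raise ValueError(f"control treatment {control!r} not present; have {treatments}")
    if len(treatments) < 2:
        raise ValueError(f"need at least 2 treatments, got {treatments}")
    counts = per_subject.groupby("treatment")["embryo_id"].nunique()
    low = counts[counts < MIN_EMBRYOS_PER_TREATMENT]
    if not low.empty:
        raise ValueError(
            f"fewer than {MIN_EMBRYOS_PER_TREATMENT} embryos per treatment for "
            f"{dict(low)}; at least {MIN_EMBRYOS_PER_TREATMENT} embryos per "
            "treatment are required for the statistical comparison"
        )

    wide = per_subject.pivot_table(
        index=["treatment", "embryo_id"], columns="coarse_bin", values="density", observed=True,
    ).sort_index()
    Y = wide.to_numpy(dtype=np.float64)
    groups = wide.index.get_level_values("treatment").to_numpy()

    anova = _mixed_anova(Y, groups)
    eps = None
    if gg:
        eps = _gg_epsilon(Y, groups)
        for effect in ("distance", "treatment_x_distance"):
            i = anova.index[anova["effect"] == effect][0]
            df1 = anova.at[i, "df"] * eps
            df2 = anova.at[i, "df_error"] * eps
            anova.at[i, "p"] = float(sps.f.sf(anova.at[i, "F"], df1, df2))

    trow = anova[anova["effect"] == "treatment"].iloc[0]

    # Dunnett many-to-one, per coarse bin
    bin_ids = sorted(per_subject["coarse_bin"].unique())
    others = [t for t in treatments if t != control]
    drows = []
    for b in bin_ids:
        sub = per_subject[per_subject["coarse_bin"] == b]
        ctrl_vals = sub.loc[sub["treatment"] == control, "density"].to_numpy()
        samples = [sub.loc[sub["treatment"] == t, "density"].to_numpy() for t in others]
        # bins where every subject has the identical value (e.g. the fully
        # saturated innermost bin, or empty distal bins) have zero pooled
        # variance: no evidence of a difference, reported as p = 1.
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.dunnett(*samples, control=ctrl_vals)
        n_total = sum(s.size for s in samples) + ctrl_vals.size
        df_t = n_total - (len(samples) + 1)
        for t, stat, p_adj in zip(others, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
            if not np.isfinite(stat):
                vals_t = sub.loc[sub["treatment"] == t, "density"].to_numpy()
                if np.ptp(np.concatenate([vals_t, ctrl_vals])) == 0:
                    stat, p_adj = 0.0, 1.0
            p_unadj = float(2.0 * sps.t.sf(abs(stat), df_t)) if np.isfinite(stat) else float("nan")
            vals = sub.loc[sub["treatment"] == t, "density"].to_numpy()
            drows.append({
                "bin_start_um": b * coarse_width_um,
                "bin_end_um": (b + 1) * coarse_width_um,
                "treatment": t,
                "control": control,
                "mean_treatment": float(vals.mean()),
                "mean_control": float(ctrl_vals.mean()),
                "mean_diff": float(vals.mean() - ctrl_vals.mean()),
                "statistic": float(stat),
                "p_unadjusted": p_unadj,
                "p_adjusted": float(p_adj),
            })
    dunnett = pd.DataFrame(drows)

    return AnovaResult(
        F_treatment=float(trow["F"]),
        df_num=int(trow["df"]),
        df_den=int(trow["df_error"]),
        p_treatment=float(trow["p"]),
        anova_table=anova,
        dunnett=dunnett,
        control_treatment=control,
        coarse_width_um=float(coarse_width_um),
        gg_epsilon=eps,
    )
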