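"""Group-level statistics: repeated-measures ANOVA across the three
recording conditions, Benjamini-Hochberg FDR within parameter families, and
Pearson correlations of drug-induced parameter changes with clinical change.

Parameter families mirror the analysis plan: extrinsic connectivity (4
members), intrinsic connectivity (8), receptor time constants (6).  FDR is
applied within each family separately.  Time-constant members are reported
on the tau = 1/kappa scale (latent sign flipped), so a negative change is a
faster receptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FAMILIES",
    "StatReport",
    "rm_anova",
    "bh_fdr",
    "pearson_correlation",
    "extract_member",
    "fits_to_frame",
    "run_group_analysis",
]

CONDITIONS = ("pre", "bolus", "infusion")

# member -> underlying latent name and sign (+1 identity, -1 for tau = -kappa
# on the log scale)
FAMILIES: dict[str, dict[str, tuple[str, int]]] = {
    "extrinsics": {
        "AMPA forward": ("ext_ampa_fwd", 1),
        "AMPA backward": ("ext_ampa_bwd", 1),
        "NMDA forward": ("ext_nmda_fwd", 1),
        "NMDA backward": ("ext_nmda_bwd", 1),
    },
    "intrinsics": {
        f"{node.capitalize()} {label}": (f"g_{node}_{edge}", 1)
        for node in ("frontal", "parietal")
        for label, edge in (("SP to SP", "sp_sp"), ("SI to SP", "si_sp"),
                            ("RL to SS", "rl_ss"), ("TP to RL", "tp_rl"))
    },
    "time_constants": {
        f"{node.capitalize()} {rec.upper() if rec != 'gaba' else 'GABA'}":
            (f"kappa_{node}_{rec}", -1)
        for node in ("frontal", "parietal")
        for rec in ("ampa", "gaba", "nmda")
    },
}


@dataclass
class StatReport:
    """Table-shaped group-analysis output."""

    anova: pd.DataFrame          # family, parameter, F, dfs, p, p_fdr
    correlations: pd.DataFrame   # parameter, timepoint, r, p, p_fdr, n

    def to_csv(self, anova_path, corr_path) -> None:
        self.anova.to_csv(anova_path, index=False)
        self.correlations.to_csv(corr_path, index=False)

    def render(self) -> str:
        out = ["Thalamocortical model parameter changes",
               "=" * 56]
        for fam, block in self.anova.groupby("family", sort=False):
            out.append(fam)
            for _, r in block.iterrows():
                out.append(
                    f"  {r.parameter:<22s} F({r.df1:.0f},{r.df2:.0f}) = "
                    f"{r.F:7.2f}   p = {r.p:.2e}   "
                    f"p_FDR = {r.p_fdr:.2e}")
        if len(self.correlations):
            out.append("Correlations with MADRS change")
            for _, r in self.correlations.iterrows():
                out.append(
                    f"  {r.parameter:<22s} {r.timepoint:>4s}  r = {r.r:+.2f}"
                    f"   p = {r.p:.3f}   p_FDR = {r.p_fdr:.3f}   n = {r.n:.0f}")
        return "\n".join(out)


def rm_anova(values: np.ndarray):
    """One-way within-subject ANOVA over an (n_subjects, k) matrix.

    F = MS_condition / MS_(condition x subject).  The primary p-value uses
    the univariate dfs (k-1, (k-1)(n-1)); the multivariate-convention dfs
    (k-1, n-k+1) and their p are reported alongside, mirroring the printed
    convention of repeated-measures software output.
    """
    x = np.asarray(values, float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need an (n >= 3 subjects, k conditions) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells in the repeated-measures design")
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_tot = float(((x - grand) ** 2).sum())
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    # sums of squares below round-off of the totals count as exactly zero
    tiny = 1e-12 * max(ss_tot, 1e-300)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = 0.0 if ss_cond <= tiny else ss_cond / df1
    ms_err = ss_err / df2
    if ms_cond == 0.0:
        F = 0.0
    elif ms_err <= tiny:
        F = np.inf
    else:
        F = ms_cond / ms_err
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    df2_mv = n - k + 1
    p_mv = float(sps.f.sf(F, df1, df2_mv)) if np.isfinite(F) else 0.0
    return {"F": float(F), "df1": df1, "df2": df2, "p": p,
            "df2_mv": df2_mv, "p_mv": p_mv}


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def pearson_correlation(x, y):
    """Sample Pearson r with two-sided t-test on n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def fits_to_frame(fits: dict) -> pd.DataFrame:
    """Flatten {subject: {condition: InversionResult | latent vector or
    mapping}} into a long frame of posterior means."""
    rows = []
    for subject, conds in fits.items():
        for cond, res in conds.items():
            if hasattr(res, "mu"):
                pairs = zip(res.names, res.mu)
            elif isinstance(res, dict):
                pairs = res.items()
            else:
                raise TypeError(f"unsupported fit payload for {subject}/{cond}")
            for name, val in pairs:
                rows.append((subject, cond, name, float(val)))
    return pd.DataFrame(rows, columns=["subject", "condition", "latent",
                                       "value"])


def extract_member(frame: pd.DataFrame, latent: str, sign: int) -> pd.DataFrame:
    """(subjects x conditions) matrix of one family member, on report scale."""
    sub = frame[frame.latent == latent]
    mat = sub.pivot(index="subject", columns="condition", values="value")
    missing = [c for c in CONDITIONS if c not in mat.columns]
    if missing or mat.isna().any().any():
        raise ValueError(f"missing subject/condition cells for {latent}")
    return sign * mat[list(CONDITIONS)]


def run_group_analysis(fits, clinical: pd.DataFrame | None = None,
                       families: dict | None = None,
                       alpha: float = 0.05) -> StatReport:
    """Full group pipeline on per-subject, per-condition fitted parameters.

    Runs the within-subject ANOVA for every family member, adjusts p-values
    within family by BH-FDR, then correlates the infusion-minus-pre change
    of every member significant before correction with the clinical change
    at 24 h and 7 days; the correlation p-values are FDR-adjusted as a set.
    """
    if families is None:
        families = FAMILIES
    frame = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)

    rows = []
    members = {}
    for fam, mem in families.items():
        for label, (latent, sign) in mem.items():
            mat = extract_member(frame, latent, sign)
            res = rm_anova(mat.to_numpy())
            members[label] = mat
            rows.append({"family": fam, "parameter": label, "latent": latent,
                         **res})
    anova = pd.DataFrame(rows)
    anova["p_fdr"] = np.concatenate([
        bh_fdr(anova.loc[anova.family == fam, "p"].to_numpy())
        for fam in families])

    corr_rows = []
    if clinical is not None and len(clinical) >= 4:
        clin = clinical.set_index("subject")
        hits = anova[anova.p < alpha]
        for _, row in hits.iterrows():
            mat = members[row.parameter]
            change = (mat["infusion"] - mat["pre"])
            for tp in ("24h", "7d"):
                col = f"change_{tp}"
                if col not in clin.columns:
                    continue
                y = clin.loc[mat.index, col].to_numpy()
                r, p = pearson_correlation(change.to_numpy(), y)
                corr_rows.append({"parameter": row.parameter,
                                  "timepoint": tp, "r": r, "p": p,
                                  "n": change.size})
    correlations = pd.DataFrame(
        corr_rows, columns=["parameter", "timepoint", "r", "p", "n"])
    if len(correlations):
        correlations["p_fdr"] = bh_fdr(correlations["p"].to_numpy())
    else:
        correlations["p_fdr"] = np.array([], dtype=float)
    return StatReport(anova=anova, correlations=correlations)
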