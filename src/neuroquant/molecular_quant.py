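"""Efficiency-corrected qPCR quantification, ChIP enrichment, blot
normalization, and the localization/colocalization statistics.

Relative expression follows the ddCt method with per-gene amplification
efficiencies from standard-curve slopes (E = 10**(-1/slope)) and
multi-reference normalization: the normalization factor is the geometric mean
of the reference-gene relative quantities (default references GAPDH, ACTB,
HPRT1), whose stability is scored with the geNorm measure M.  ChIP-qPCR is
expressed as percent input and fold enrichment over a control condition.
Imaging statistics are the spine/shaft relative difference (S-D)/(S+D) and
thresholded Manders colocalization coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CT_COLUMNS = ("sample_id", "group", "gene", "ct")

#: Replicate scatter above this many cycles is flagged for review.
REPLICATE_SD_FLAG = 0.5


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return ct


def _validate_eff(efficiencies: dict[str, float], genes) -> None:
    for g in genes:
        if g not in efficiencies:
            raise ValueError(f"no amplification efficiency for gene {g!r}")
        e = efficiencies[g]
        if not 1.0 < e <= 2.2:
            raise ValueError(f"efficiency for {g!r} out of range (1, 2.2]: {e}")


def mean_ct(ct: pd.DataFrame, flag_sd: float = REPLICATE_SD_FLAG) -> pd.DataFrame:
    """Average technical replicates per (sample, gene); flag noisy triplicates."""
    _validate_ct(ct)
    g = ct.groupby(["sample_id", "group", "gene"], sort=True)["ct"]
    out = g.agg(ct="mean", ct_sd="std", n_replicates="size").reset_index()
    out["ct_sd"] = out["ct_sd"].fillna(0.0)
    out["flagged"] = out["ct_sd"] > flag_sd
    return out


@dataclass(frozen=True)
class EfficiencyFit:
    gene: str
    slope: float  # cycles per log10(input)
    efficiency: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("a valid standard curve has a negative slope")


def fit_efficiency(log10_input, ct, gene: str = "") -> EfficiencyFit:
    """Standard-curve efficiency from a serial dilution: E = 10**(-1/slope)."""
    x = np.asarray(log10_input, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size < 3 or np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct dilution points")
    res = sps.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(f"invalid standard curve for {gene or 'gene'}: "
                         f"non-negative slope {res.slope:.3g}")
    return EfficiencyFit(gene, float(res.slope),
                         float(10.0 ** (-1.0 / res.slope)),
                         float(res.rvalue**2))


def _relative_quantities(means: pd.DataFrame, efficiencies: dict[str, float]
                         ) -> pd.DataFrame:
    """Per-gene Q = E**(min Ct - Ct) across samples (geNorm convention)."""
    out = means.copy()
    ref_ct = means.groupby("gene")["ct"].transform("min")
    e = means["gene"].map(efficiencies)
    out["q"] = e ** (ref_ct - means["ct"])
    return out


def genorm_stability(
    ct: pd.DataFrame,
    candidate_refs: list[str],
    efficiencies: dict[str, float],
) -> pd.Series:
    """geNorm stability M per candidate reference gene (lower = more stable).

    M_j is the mean over the other candidates k of the SD across samples of
    log2(Q_j / Q_k).
    """
    if len(candidate_refs) < 3:
        raise ValueError("geNorm stability needs at least 3 candidate genes")
    _validate_eff(efficiencies, candidate_refs)
    means = mean_ct(ct)
    means = means[means["gene"].isin(candidate_refs)]
    if means["sample_id"].nunique() < 2:
        raise ValueError("geNorm stability needs at least 2 samples")
    q = _relative_quantities(means, efficiencies)
    wide = q.pivot_table(index="sample_id", columns="gene", values="q")
    if wide.isna().any().any():
        raise ValueError("every candidate gene must be measured in every sample")
    logq = np.log2(wide)
    m = {}
    for g in candidate_refs:
        others = [k for k in candidate_refs if k != g]
        m[g] = float(np.mean([logq[g].sub(logq[k]).std(ddof=1) for k in others]))
    return pd.Series(m, name="M").sort_values()


def relative_expression(
    ct: pd.DataFrame,
    refs: list[str],
    calibrator_group: str,
    efficiencies: dict[str, float],
) -> pd.DataFrame:
    """Efficiency-corrected ddCt expression with multi-reference normalization.

    For each gene, Q = E**(mean calibrator Ct - sample Ct); the normalization
    factor NF is the geometric mean of the reference-gene Q values of the
    sample; normalized expression is Q_target / NF rescaled so that the
    calibrator-group mean is exactly 1.  Samples missing a reference
    measurement are dropped with a reason recorded in the ``dropped`` attr.
    """
    means = mean_ct(ct)
    genes = means["gene"].unique()
    _validate_eff(efficiencies, genes)
    if calibrator_group not in set(means["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent from table")
    missing_refs = set(refs) - set(genes)
    if missing_refs:
        raise ValueError(f"reference genes absent from table: {sorted(missing_refs)}")

    wide = means.pivot_table(index=["sample_id", "group"], columns="gene",
                             values="ct")
    dropped = []
    ok = wide[refs].notna().all(axis=1)
    for (sid, _grp) in wide.index[~ok]:
        dropped.append((sid, "missing reference measurement"))
    wide = wide[ok]

    cal = wide[wide.index.get_level_values("group") == calibrator_group]
    if cal.empty:
        raise ValueError("no calibrator samples left after exclusions")
    cal_mean = cal.mean(axis=0)

    q = pd.DataFrame(index=wide.index)
    for g in genes:
        q[g] = efficiencies[g] ** (cal_mean[g] - wide[g])
    nf = np.exp(np.log(q[refs]).mean(axis=1))  # geometric mean

    records = []
    targets = [g for g in genes if g not in refs] or list(genes)
    for g in targets:
        norm = q[g] / nf
        cal_norm = norm[norm.index.get_level_values("group") == calibrator_group]
        scale = cal_norm.mean()
        for (sid, grp), val in norm.items():
            records.append({
                "sample_id": sid, "group": grp, "gene": g,
                "q": float(q.loc[(sid, grp), g]),
                "nf": float(nf.loc[(sid, grp)]),
                "normalized": float(val / scale),
            })
    out = pd.DataFrame(records)
    out.attrs["dropped"] = dropped
    return out


def chip_fold_enrichment(
    ct: pd.DataFrame,
    input_dilution: float,
    efficiency: float = 2.0,
    control_group: str = "control",
) -> pd.DataFrame:
    """Percent input and fold enrichment over the control condition.

    The table needs columns sample_id, group, fraction ('ip' or 'input'), ct,
    and optionally 'target' for multiple regions.  Percent input adjusts the
    input Ct for its dilution: %input = 100 * E**((Ct_input - log_E(dilution))
    - Ct_IP); fold enrichment is the group-mean %input over the control
    group-mean %input.
    """
    required = {"sample_id", "group", "fraction", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"ChIP table lacks columns {sorted(required - set(ct.columns))}")
    if input_dilution <= 0:
        raise ValueError("input dilution factor must be positive")
    if not 1.0 < efficiency <= 2.2:
        raise ValueError("efficiency out of range (1, 2.2]")
    df = ct.copy()
    if "target" not in df.columns:
        df["target"] = "target"
    dilution_cycles = np.log(input_dilution) / np.log(efficiency)
    rows = []
    for (target, group, sid), sub in df.groupby(["target", "group", "sample_id"]):
        ip = sub.loc[sub["fraction"] == "ip", "ct"]
        inp = sub.loc[sub["fraction"] == "input", "ct"]
        if ip.empty or inp.empty:
            raise ValueError(f"missing IP or input Ct for sample {sid!r} ({target})")
        pct = 100.0 * efficiency ** ((inp.mean() - dilution_cycles) - ip.mean())
        rows.append({"target": target, "group": group, "sample_id": sid,
                     "percent_input": float(pct)})
    out = pd.DataFrame(rows)
    ctrl = out[out["group"] == control_group].groupby("target")["percent_input"].mean()
    if ctrl.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    out["fold_enrichment"] = out.apply(
        lambda r: r["percent_input"] / ctrl[r["target"]], axis=1
    )
    return out


def normalize_to_control(
    values: pd.Series | dict[str, float],
    control_ids: list[str],
    phospho_total: dict[str, str] | None = None,
) -> pd.Series:
    """Fold band intensities over the control mean (per-membrane rule).

    With ``phospho_total`` mapping phospho-band ids to total-band ids, the
    phospho/total ratio is formed before control normalization.
    """
    v = pd.Series(values, dtype=float)
    if phospho_total:
        ratios = {}
        for ph, tot in phospho_total.items():
            if v[tot] == 0:
                raise ValueError(f"total band {tot!r} has zero intensity")
            ratios[ph] = v[ph] / v[tot]
        v = pd.Series(ratios, dtype=float)
    missing = [c for c in control_ids if c not in v.index]
    if missing:
        raise ValueError(f"control ids absent: {missing}")
    ctrl = v[control_ids].mean()
    if ctrl <= 0:
        raise ValueError("control mean must be positive")
    return v / ctrl


def relative_difference(s: float, d: float) -> float:
    """Spine/shaft localization statistic (S - D) / (S + D) in [-1, 1].

    +1 means fully synaptic (spine) localization, -1 fully dendritic (shaft).
    Pairs with non-positive total signal after background subtraction are
    excluded (raises ValueError).
    """
    if s < 0 or d < 0 or s + d <= 0:
        raise ValueError("require S >= 0, D >= 0 and S + D > 0; pair excluded")
    return (s - d) / (s + d)


def manders_coefficient(a, b, t_a: float, t_b: float) -> tuple[float, float]:
    """Thresholded Manders colocalization coefficients (M_A, M_B).

    M_A is the summed channel-A intensity over pixels where both channels
    exceed their thresholds, divided by the summed A intensity over pixels
    where A exceeds t_A (symmetrically for M_B).  A channel with no pixel
    above threshold has an undefined coefficient (NaN).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("channels must have the same number of pixels")
    if t_a < 0 or t_b < 0:
        raise ValueError("thresholds must be non-negative")
    mask_a = a > t_a
    mask_b = b > t_b
    both = mask_a & mask_b
    m_a = float(a[both].sum() / a[mask_a].sum()) if mask_a.any() else float("nan")
    m_b = float(b[both].sum() / b[mask_b].sum()) if mask_b.any() else float("nan")
    return m_a, m_b
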