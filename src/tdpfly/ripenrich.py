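"""RNA-IP enrichment post-processing.

Candidate mRNA targets of TDP-43 are genes enriched in the IP library over
the brain transcriptome (input) at Log2FC > 1 and adjusted p < 0.05 (strict
inequalities).  Nonspecific pull-down is handled by subtracting the
log2 fold changes observed with a tag-only (YFP) control IP.  Cross-model
comparisons use exact set algebra; RT-qPCR validation uses the 2^(-ddCt)
fold change; patient single-nucleus comparisons contrast nuclei carrying
cryptic exons (a molecular signature of nuclear TDP-43 loss) against nuclei
with canonical junctions via an independent two-sample t-test.

The enrichment test here is a deliberately simple per-gene negative-binomial
Wald test with median-of-ratios normalization and method-of-moments
dispersion.  It is NOT numerically identical to a full shrinkage-based DE
fit; externally produced DE tables (gene_id, log2FC, padj) can be ingested
directly to bypass it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .statcore import TestResult, bh_adjust

__all__ = [
    "OverlapReport",
    "QpcrResult",
    "size_factors",
    "enrichment_test",
    "yfp_subtract",
    "candidate_filter",
    "overlap",
    "overlap_from_sizes",
    "ddct_fold_change",
    "ortholog_join",
    "cryptic_group_compare",
]


# --------------------------------------------------------------------------
# normalization and the simplified enrichment test


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Only genes with nonzero counts in every sample enter the median.  With a
    single sample the factor is 1.
    """
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = counts.loc[pos].to_numpy(float)
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def _mom_dispersion(block: np.ndarray, inv_sf: float) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion of one condition's
    normalized counts: alpha = (s^2 - mean/sf) / mean^2, floored at 0."""
    mean = block.mean(axis=1)
    var = block.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean * inv_sf) / mean**2
    return np.where(np.isfinite(alpha), np.maximum(alpha, 0.0), 0.0)


def enrichment_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    ip_condition: str = "tdp_ip",
    ref_condition: str = "input",
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Per-gene IP-vs-input enrichment with a simplified NB Wald test.

    Counts are normalized by median-of-ratios size factors; the statistic is
    the log-ratio of condition means with a delta-method standard error
    using per-gene method-of-moments dispersion (floored at the across-gene
    median so single-gene dispersion collapse cannot inflate significance).
    p-values are BH-adjusted across tested genes; genes with zero counts in
    every used sample are excluded from testing (reported with NaN).

    Returns a frame indexed by gene with columns log2FC, p, padj, mean_ip,
    mean_ref, dispersion, tested.
    """
    use = samples[samples["condition"].isin([ip_condition, ref_condition])]
    if (use.groupby("condition").size() < 2).any() or use["condition"].nunique() < 2:
        raise ValueError("need >= 2 replicates in both tested conditions")
    cols = use["sample"].tolist()
    sf = size_factors(counts[cols])
    norm = counts[cols].to_numpy(float) / sf.to_numpy()[None, :]
    is_ip = (use["condition"] == ip_condition).to_numpy()
    ip, ref = norm[:, is_ip], norm[:, ~is_ip]
    n_ip, n_ref = ip.shape[1], ref.shape[1]
    m_ip, m_ref = ip.mean(axis=1), ref.mean(axis=1)

    tested = (m_ip + m_ref) > 0
    inv_sf_ip = float(np.mean(1.0 / sf.to_numpy()[is_ip]))
    inv_sf_ref = float(np.mean(1.0 / sf.to_numpy()[~is_ip]))
    alpha = (_mom_dispersion(ip, inv_sf_ip) + _mom_dispersion(ref, inv_sf_ref)) / 2.0
    med = float(np.median(alpha[tested])) if tested.any() else 0.0
    alpha = np.maximum(alpha, med)

    pc = pseudo_count
    log2fc = np.log2((m_ip + pc) / (m_ref + pc))
    var_mip = (m_ip * inv_sf_ip + alpha * m_ip**2) / n_ip
    var_mref = (m_ref * inv_sf_ref + alpha * m_ref**2) / n_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        se_log = np.sqrt(var_mip / (m_ip + pc) ** 2 + var_mref / (m_ref + pc) ** 2)
        z = np.log((m_ip + pc) / (m_ref + pc)) / se_log
    p = np.where(tested, 2 * stats.norm.sf(np.abs(z)), np.nan)
    padj = np.full(p.shape, np.nan)
    padj[tested] = bh_adjust(p[tested])
    return pd.DataFrame(
        {
            "log2FC": np.where(tested, log2fc, np.nan),
            "p": p,
            "padj": padj,
            "mean_ip": m_ip,
            "mean_ref": m_ref,
            "dispersion": alpha,
            "tested": tested,
        },
        index=counts.index,
    )


# --------------------------------------------------------------------------
# YFP subtraction and candidate filtering


def yfp_subtract(tdp: pd.DataFrame, yfp: pd.DataFrame) -> pd.DataFrame:
    """Subtract tag-only control log2FC from the target log2FC, by gene.

    Genes absent from the control table get yfp_log2FC = 0 (no evidence of
    nonspecific binding) and are flagged ``yfp_missing``.
    """
    out = tdp.copy()
    y = yfp["log2FC"].reindex(out.index)
    out["yfp_missing"] = y.isna()
    out["yfp_log2FC"] = y.fillna(0.0)
    out["adjusted_log2FC"] = out["log2FC"] - out["yfp_log2FC"]
    return out


def candidate_filter(
    records: pd.DataFrame,
    log2fc_min: float = 1.0,
    padj_max: float = 0.05,
    mode: str = "raw",
) -> set:
    """Candidate targets: log2FC strictly above and padj strictly below threshold.

    ``mode="raw"`` filters on the model's own log2FC; ``mode="adjusted"``
    on the YFP-subtracted value.  Strictness is deliberate: a gene at
    exactly log2FC = 1 is excluded.
    """
    col = {"raw": "log2FC", "adjusted": "adjusted_log2FC"}[mode]
    if col not in records.columns:
        raise ValueError(f"records lack column {col!r}")
    keep = (records[col] > log2fc_min) & (records["padj"] < padj_max)
    keep &= records[col].notna() & records["padj"].notna()
    return set(records.index[keep])


# --------------------------------------------------------------------------
# set overlap bookkeeping


@dataclass
class OverlapReport:
    size_a: int
    size_b: int
    shared: int
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self):
        if self.shared > min(self.size_a, self.size_b) or self.shared < 0:
            raise ValueError("shared exceeds a set size")

    @property
    def union(self) -> int:
        return self.size_a + self.size_b - self.shared

    @property
    def unique_a(self) -> int:
        return self.size_a - self.shared

    @property
    def unique_b(self) -> int:
        return self.size_b - self.shared

    @property
    def pct_shared_of_a(self) -> float:
        return 100.0 * self.shared / self.size_a if self.size_a else float("nan")

    @property
    def pct_shared_of_b(self) -> float:
        return 100.0 * self.shared / self.size_b if self.size_b else float("nan")

    def summary(self) -> dict:
        """Report dict; percentages rounded to the nearest integer for
        display, full precision retained on the properties."""
        return {
            "size_a": self.size_a,
            "size_b": self.size_b,
            "shared": self.shared,
            "union": self.union,
            "unique_a": self.unique_a,
            "unique_b": self.unique_b,
            "pct_shared_of_a": round(self.pct_shared_of_a),
            "pct_shared_of_b": round(self.pct_shared_of_b),
        }


def overlap(set_a, set_b, label_a: str = "A", label_b: str = "B") -> OverlapReport:
    """Exact set-overlap arithmetic between two candidate-target sets."""
    a, b = set(set_a), set(set_b)
    return OverlapReport(len(a), len(b), len(a & b), label_a, label_b)


def overlap_from_sizes(
    size_a: int, size_b: int, shared: int, label_a: str = "A", label_b: str = "B"
) -> OverlapReport:
    """Overlap bookkeeping from published sizes and intersection."""
    return OverlapReport(size_a, size_b, shared, label_a, label_b)


# --------------------------------------------------------------------------
# RT-qPCR fold change


@dataclass
class QpcrResult:
    """2^(-ddCt) fold change of a target vs a reference gene, IP vs input.

    dCt = Ct_target - Ct_reference within each condition (triplicate wells
    averaged first); ddCt = dCt_IP - dCt_input; FC = 2^(-ddCt), so
    log2(FC) = -ddCt exactly and ddCt = 0 gives FC = 1.
    """

    delta_ct_ip: float
    delta_ct_input: float

    @property
    def delta_delta_ct(self) -> float:
        return self.delta_ct_ip - self.delta_ct_input

    @property
    def fold_change(self) -> float:
        return float(2.0 ** (-self.delta_delta_ct))


def ddct_fold_change(
    ct_target_ip, ct_reference_ip, ct_target_input, ct_reference_input
) -> QpcrResult:
    """Fold change from raw Ct values (arrays of replicate wells or scalars)."""
    vals = [
        np.mean(np.asarray(v, dtype=float))
        for v in (ct_target_ip, ct_reference_ip, ct_target_input, ct_reference_input)
    ]
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    t_ip, r_ip, t_in, r_in = vals
    return QpcrResult(delta_ct_ip=t_ip - r_ip, delta_ct_input=t_in - r_in)


# --------------------------------------------------------------------------
# ortholog joins and patient single-nucleus comparison


def ortholog_join(
    fly_records: pd.DataFrame,
    ortholog_table: pd.DataFrame,
    fly_col: str = "fly_id",
    human_col: str = "human_id",
    score_col: str = "score",
    best_score_only: bool = False,
) -> pd.DataFrame:
    """Left-join fly genes onto a supplied ortholog map.

    Many-to-many mappings are preserved (one row per pair); unmapped fly
    genes are retained with a null ortholog.  ``best_score_only`` keeps only
    the top-scoring ortholog(s) per fly gene.
    """
    om = ortholog_table.copy()
    if best_score_only and score_col in om.columns:
        best = om.groupby(fly_col)[score_col].transform("max")
        om = om[om[score_col] == best]
    joined = fly_records.merge(om, on=fly_col, how="left")
    dup = joined.duplicated(subset=[fly_col], keep=False) & joined[human_col].notna()
    joined.attrs["n_multi_mapped"] = int(joined.loc[dup, fly_col].nunique())
    return joined


def cryptic_group_compare(
    expr: pd.DataFrame,
    gene: str,
    group_col: str = "group",
    cryptic_label: str = "cryptic",
    canonical_label: str = "canonical",
    equal_var: bool = True,
) -> tuple[dict, TestResult]:
    """Compare a gene's log-normalized expression between nuclei carrying a
    cryptic exon and nuclei with canonical junctions.

    Uses the independent two-sample t-test (pooled variance by default,
    mirroring the cited function's default).  Returns the per-group means
    and the test result.
    """
    for lab in (cryptic_label, canonical_label):
        if not (expr[group_col] == lab).any():
            raise ValueError(f"group {lab!r} is empty")
    a = expr.loc[expr[group_col] == cryptic_label, gene].to_numpy(float)
    b = expr.loc[expr[group_col] == canonical_label, gene].to_numpy(float)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    means = {
        cryptic_label: float(a.mean()),
        canonical_label: float(b.mean()),
        "n_cryptic": int(a.size),
        "n_canonical": int(b.size),
    }
    return means, TestResult(
        method="independent-t" + ("" if equal_var else "-welch"),
        comparison=(cryptic_label, canonical_label),
        statistic=float(t),
        p_value=float(p),
    )
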