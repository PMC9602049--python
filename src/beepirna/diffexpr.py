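"""Expression normalisation and differential-expression calling.

Counts are normalised to tags per million (TPM = T * 1e6 / N, with N the
library's total clean small-RNA tags). Fold changes are log2 ratios of pooled
group TPMs, with a configurable floor replacing zero TPMs. Significance uses
the Audic-Claverie conditional test on pooled counts by default (Welch's
t-test on replicate TPMs as an option), and a piRNA is called differentially
expressed when p <= 0.05 and |log2FC| >= 1 (both boundaries inclusive).

The Audic-Claverie conditional distribution of y given x with library sizes
N1, N2 is negative-binomial with x+1 successes and success probability
N1/(N1+N2); tails are computed from that identity. Under replicate-level
overdispersion the raw pooled-count p is anticonservative; the joint
p-and-fold-change rule is what controls the practical false-positive rate.

A 2^-ddCt calculator converts qPCR cycle thresholds into relative expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_LOG2FC_THRESHOLD = 1.0
DEFAULT_TPM_FLOOR = 0.01


@dataclass
class ComparisonSpec:
    """A named two-group comparison, numerator over denominator.

    The conventional naming is "earlier vs later" with the later group in the
    numerator (e.g. "Am4 vs Am5" ranks Am5 relative to Am4).
    """

    name: str
    numerator: str
    denominator: str
    test: str = "pooled-count"  # or "welch-t"
    zero_tpm_floor: float = DEFAULT_TPM_FLOOR

    def __post_init__(self):
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator groups must differ")
        if self.zero_tpm_floor <= 0:
            raise ValueError("zero_tpm_floor must be positive")
        if self.test not in {"pooled-count", "welch-t"}:
            raise ValueError(f"unknown test {self.test!r}")


def tpm_normalize(counts, library_sizes):
    """Tags-per-million normalisation, elementwise T * 1e6 / N.

    `counts` may be a scalar, array, or DataFrame (features x replicates);
    `library_sizes` a scalar or per-replicate mapping/Series. N must be > 0.
    """
    if isinstance(counts, pd.DataFrame):
        sizes = pd.Series(library_sizes)[counts.columns].astype(float)
        if (sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        return counts * 1e6 / sizes
    n = np.asarray(library_sizes, dtype=float)
    if np.any(n <= 0):
        raise ValueError("library sizes must be positive")
    out = np.asarray(counts, dtype=float) * 1e6 / n
    return float(out) if np.isscalar(counts) else out


def fold_change(tpm_num, tpm_den, floor: float = DEFAULT_TPM_FLOOR):
    """log2 fold change of floored TPMs; exactly antisymmetric in arguments."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    num = np.maximum(np.asarray(tpm_num, dtype=float), floor)
    den = np.maximum(np.asarray(tpm_den, dtype=float), floor)
    # difference of logs keeps antisymmetry exact in floating point
    out = np.log2(num) - np.log2(den)
    return float(out) if out.ndim == 0 else out


def ac_pvalue(x, y, n1: float = 1.0, n2: float = 1.0, tail_method: str = "double"):
    """Audic-Claverie two-sided p-value for pooled counts x vs y.

    x is observed in a library of size n1, y in a library of size n2. With
    tail_method="double" the smaller of the two inclusive tails is doubled
    (capped at 1); "minlike" sums the probability of all outcomes no more
    likely than the observed one (the convention Fisher-style exact tests
    use). Vectorised over x and y for "double".
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    p_success = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p_success)
    upper = stats.nbinom.sf(y - 1, x + 1, p_success)
    if tail_method == "double":
        p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
        return float(p) if p.ndim == 0 else p
    if tail_method != "minlike":
        raise ValueError(f"unknown tail_method {tail_method!r}")
    if x.ndim or y.ndim:
        raise ValueError("minlike tail is scalar-only")
    # sum pmf over all y' with pmf(y') <= pmf(y) * (1 + 1e-7)
    obs = stats.nbinom.pmf(int(y), int(x) + 1, p_success)
    cutoff = obs * (1 + 1e-7)
    # enumerate out to a far quantile; beyond it pmf is < cutoff and the
    # remaining mass belongs to the upper tail, handled by sf
    hi = int(stats.nbinom.isf(1e-16, int(x) + 1, p_success)) + 2
    ys = np.arange(hi + 1)
    pmf = stats.nbinom.pmf(ys, int(x) + 1, p_success)
    p = pmf[pmf <= cutoff].sum() + stats.nbinom.sf(hi, int(x) + 1, p_success)
    return float(min(1.0, p))


def de_test(counts_num, counts_den, spec: ComparisonSpec, lib_num=None, lib_den=None):
    """Per-feature p-values for one comparison.

    pooled-count: Audic-Claverie on pooled counts with pooled library sizes.
    welch-t: Welch's t on replicate TPMs (needs >= 2 replicates per group).
    Inputs are arrays (features x replicates) of raw counts plus library
    sizes; returns (p-values, all_zero warning flags).
    """
    counts_num = np.atleast_2d(np.asarray(counts_num, dtype=float))
    counts_den = np.atleast_2d(np.asarray(counts_den, dtype=float))
    if lib_num is None:
        lib_num = np.ones(counts_num.shape[1])
    if lib_den is None:
        lib_den = np.ones(counts_den.shape[1])
    lib_num = np.asarray(lib_num, dtype=float)
    lib_den = np.asarray(lib_den, dtype=float)
    all_zero = (counts_num.sum(axis=1) == 0) & (counts_den.sum(axis=1) == 0)
    if spec.test == "pooled-count":
        # The conditional test is orientation-asymmetric; evaluate it in a
        # canonical orientation so reversing a comparison preserves p exactly.
        x = counts_den.sum(axis=1)
        y = counts_num.sum(axis=1)
        n1, n2 = lib_den.sum(), lib_num.sum()
        p_fwd = ac_pvalue(x, y, n1=n1, n2=n2)
        p_rev = ac_pvalue(y, x, n1=n2, n2=n1)
        use_fwd = (x < y) | ((x == y) & (n1 <= n2))
        p = np.where(use_fwd, p_fwd, p_rev)
    else:
        if counts_num.shape[1] < 2 or counts_den.shape[1] < 2:
            raise ValueError("welch-t needs >= 2 replicates per group")
        tpm_n = counts_num * 1e6 / lib_num
        tpm_d = counts_den * 1e6 / lib_den
        p = stats.ttest_ind(tpm_n, tpm_d, axis=1, equal_var=False).pvalue
        p = np.where(np.isnan(p), 1.0, p)
    p = np.where(all_zero, 1.0, p)
    return p, all_zero


def run_comparison(
    counts: pd.DataFrame,
    library_sizes,
    rep_to_group,
    spec: ComparisonSpec,
) -> pd.DataFrame:
    """Build the full expression table for one comparison.

    `counts` is features x replicates. Pooled group TPM is pooled counts over
    pooled library size. Direction: up iff log2fc >= 1 and p <= 0.05, down iff
    log2fc <= -1 and p <= 0.05, else ns.
    """
    sizes = pd.Series(library_sizes).astype(float)
    reps_num = sorted(r for r in counts.columns if rep_to_group[r] == spec.numerator)
    reps_den = sorted(r for r in counts.columns if rep_to_group[r] == spec.denominator)
    if not reps_num or not reps_den:
        raise ValueError(f"comparison {spec.name!r} references groups with no replicates")

    tpm = tpm_normalize(counts, sizes)
    pooled_num = counts[reps_num].sum(axis=1) * 1e6 / sizes[reps_num].sum()
    pooled_den = counts[reps_den].sum(axis=1) * 1e6 / sizes[reps_den].sum()
    log2fc = fold_change(pooled_num, pooled_den, floor=spec.zero_tpm_floor)
    p, warn = de_test(
        counts[reps_num].to_numpy(), counts[reps_den].to_numpy(), spec,
        lib_num=sizes[reps_num].to_numpy(), lib_den=sizes[reps_den].to_numpy(),
    )
    out = pd.DataFrame(
        {
            **{f"tpm_{r}": tpm[r] for r in counts.columns},
            f"tpm_{spec.numerator}": pooled_num,
            f"tpm_{spec.denominator}": pooled_den,
            "log2fc": log2fc,
            "p_value": p,
            "all_zero": warn,
        },
        index=counts.index,
    )
    out.index.name = "pirna_id"
    out["comparison"] = spec.name
    out["direction"] = classify_direction(out["log2fc"], out["p_value"])
    return out


def classify_direction(
    log2fc,
    p_value,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD,
):
    """up / down / ns labels with inclusive boundaries (p <= 0.05, |fc| >= 1)."""
    log2fc = np.asarray(log2fc, dtype=float)
    p_value = np.asarray(p_value, dtype=float)
    sig = p_value <= p_threshold
    out = np.where(sig & (log2fc >= fc_threshold), "up",
                   np.where(sig & (log2fc <= -fc_threshold), "down", "ns"))
    return out if out.ndim else str(out)


def call_depirnas(
    records: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD,
):
    """Rank the up- and down-regulated calls of one comparison table.

    Ranking: |log2fc| descending, then p ascending, then id. Returns
    (up table, down table).
    """
    rec = records.copy()
    rec["direction"] = classify_direction(
        rec["log2fc"], rec["p_value"], p_threshold, fc_threshold
    )
    rec["_abs_fc"] = rec["log2fc"].abs()
    rec["_id"] = rec["pirna_id"] if "pirna_id" in rec.columns else rec.index
    rec = rec.sort_values(
        ["_abs_fc", "p_value", "_id"], ascending=[False, True, True], kind="mergesort"
    ).drop(columns=["_abs_fc", "_id"])
    return rec[rec["direction"] == "up"], rec[rec["direction"] == "down"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def ddct_relative_expression(
    ct_target_test: float, ct_ref_test: float, ct_target_ctrl: float, ct_ref_ctrl: float
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,control - Ct_ref,control).
    """
    for v in (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
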