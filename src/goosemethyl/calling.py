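"""Binomial methylcytosine identification with an empirical false-positive rate.

In vertebrate WGBS data nearly all true methylation is in CG context, so the
pooled methylation rate at non-CG cytosines (CHG + CHH) measures the
false-positive background: bisulfite non-conversion plus thymidine-to-cytosine
sequencing errors.  Each covered cytosine is then tested against that
background with a one-sided binomial test — a site is a methylcytosine when
an excess of methylated reads is unlikely under the error rate alone
(p < alpha at 99% confidence by default) and its read depth is at least 4.

Phred-style Q scores relate a base-call's correctness probability p to
``Q = 10*log10(p / (1 - p))``; the conventional Q >= 20 filter therefore
guarantees a correct call in more than 99% of cases (100/101).  When the
input table carries a per-site quality column the filter is applied; calls
arriving without qualities are assumed pre-filtered upstream.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_DEPTH = 4
DEFAULT_MIN_Q = 20.0


def q_score(p_correct: float) -> float:
    """Q score of a base call with correctness probability ``p_correct``.

    Q = 10*log10(p/(1-p)); defined only for 0 < p < 1.
    """
    if not 0.0 < p_correct < 1.0:
        raise ValueError(f"p_correct must be in (0, 1), got {p_correct}")
    return 10.0 * np.log10(p_correct / (1.0 - p_correct))


def invert_q(q: float) -> float:
    """Correct-call probability corresponding to Q score ``q``.

    The inverse of :func:`q_score`: ``10^(q/10) / (1 + 10^(q/10))``.
    At q = 20 this is 100/101, the ">99% correct" guarantee behind the
    conventional Q >= 20 filter.
    """
    r = 10.0 ** (np.asarray(q, dtype=float) / 10.0)
    out = r / (1.0 + r)
    return float(out) if np.isscalar(q) else out


@dataclasses.dataclass(frozen=True)
class FalsePositiveRate:
    """Pooled non-CG methylation, the background error rate for mC calling."""

    n_mchg: int
    n_mchh: int
    n_depth: int

    @property
    def rate(self) -> float:
        return (self.n_mchh + self.n_mchg) / self.n_depth

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def estimate_false_positive_rate(calls: pd.DataFrame) -> FalsePositiveRate:
    """Estimate the false-positive rate from all covered non-CG sites.

    rate = (n_mCHH + n_mCHG) / n_depth, where the numerator sums methylated
    read counts over CHG and CHH sites and the denominator sums total read
    depth over those same sites.
    """
    non_cg = calls[calls["context"].isin(["CHG", "CHH"])]
    n_depth = int(non_cg["depth"].sum())
    if n_depth == 0:
        raise ValueError("false-positive rate undefined: zero depth at non-CG sites")
    n_mchg = int(non_cg.loc[non_cg["context"] == "CHG", "meth_count"].sum())
    n_mchh = int(non_cg.loc[non_cg["context"] == "CHH", "meth_count"].sum())
    return FalsePositiveRate(n_mchg=n_mchg, n_mchh=n_mchh, n_depth=n_depth)


def binomial_tail_p(meth_count, depth, rate):
    """Upper-tail binomial probability P(X >= meth_count | depth, rate).

    Vectorised over ``meth_count``/``depth``.  ``meth_count = 0`` gives 1.
    """
    meth_count = np.asarray(meth_count)
    depth = np.asarray(depth)
    return stats.binom.sf(meth_count - 1, depth, rate)


@dataclasses.dataclass(frozen=True)
class MCStatus:
    """Binomial-test outcome for one cytosine."""

    chrom: str
    pos: int
    strand: str
    context: str
    depth: int
    meth_count: int
    p_value: float
    is_mc: bool
    q: float = float("nan")


def call_mc(
    call,
    fp: FalsePositiveRate,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> MCStatus:
    """Test a single cytosine call against the false-positive background.

    ``call`` is any mapping with chrom/pos/strand/context/depth/meth_count.
    A site is a methylcytosine iff depth >= min_depth and the upper-tail
    binomial p-value is below alpha.  Sites failing the depth floor are
    excluded from all downstream CG statistics regardless of p.
    """
    if not 0.0 < fp.rate < 1.0:
        raise ValueError(f"false-positive rate must be in (0, 1), got {fp.rate}")
    depth = int(call["depth"])
    meth = int(call["meth_count"])
    p = float(binomial_tail_p(meth, depth, fp.rate))
    return MCStatus(
        chrom=str(call["chrom"]),
        pos=int(call["pos"]),
        strand=str(call["strand"]),
        context=str(call["context"]),
        depth=depth,
        meth_count=meth,
        p_value=p,
        is_mc=bool(depth >= min_depth and p < alpha),
    )


def call_mc_table(
    calls: pd.DataFrame,
    fp: FalsePositiveRate,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_q: float = DEFAULT_MIN_Q,
) -> pd.DataFrame:
    """Vectorised :func:`call_mc` over a whole per-sample call table.

    Adds ``p_value`` and ``is_mc`` columns.  If a ``q`` column is present,
    sites with q < min_q additionally fail the mC filter.
    """
    if not 0.0 < fp.rate < 1.0:
        raise ValueError(f"false-positive rate must be in (0, 1), got {fp.rate}")
    out = calls.copy()
    out["p_value"] = binomial_tail_p(
        out["meth_count"].to_numpy(), out["depth"].to_numpy(), fp.rate
    )
    is_mc = (out["depth"] >= min_depth) & (out["p_value"] < alpha)
    if "q" in out.columns:
        is_mc &= out["q"].astype(float) >= min_q
    out["is_mc"] = is_mc
    return out
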