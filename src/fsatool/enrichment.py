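"""Per-position class-enrichment testing and the information-scaled filter.

For one PSSM, every (position, class) pair is tested for enrichment against
the whole-protein baseline with a one-sided Mann-Whitney U test.  In the
default ``member`` sampling mode the test sample at position *i* for class
*c* is the set of member frequencies {p_i(a) : a in M_c} and the baseline is
the leave-one-out pool {p_j(a) : a in M_c, j != i}; the alternative
``class_sum`` mode compares the single summed class frequency F_i(c) against
{F_j(c) : j != i}.  Significance is a raw p < alpha (default 0.01); no
multiple-testing correction is applied by default, with Benjamini-Hochberg
available as an option.

Positions are then ranked by the filter score

    s_i = I_i * ||d_i||

where I_i is the position's information content (bits) and ||d_i|| the
Euclidean (Frobenius) norm of the difference between the position's class
vector and the protein-wide mean class vector.  Only the top
``ceil(keep_fraction * L)`` positions keep their enrichment flags; flags on
discarded positions are revoked but remain recorded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .chem import ChemClassScheme, class_frequencies
from .errors import ParameterError
from .pssm import PSSM

#: Exhaustive-enumeration cutoff for the exact U distribution.
EXACT_MAX_N = 20


def _u_statistic(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Rank-based Mann-Whitney U of the first sample (vectorized)."""
    nx = x.shape[axis]
    pooled = np.concatenate([x, y], axis=axis)
    ranks = stats.rankdata(pooled, axis=axis)
    rx = np.take(ranks, np.arange(nx), axis=axis).sum(axis=axis)
    return rx - nx * (nx + 1) / 2.0


def _exact_p_single(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Exact permutation p when one sample has a single observation.

    The null distribution of U then just re-seats that one value at every
    pooled rank, so the tail probability is a direct count.
    """
    m = len(a)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    if m == 1:
        null_u = ranks - 1.0
        u_obs = float(ranks[0] - 1.0)
    else:  # len(b) == 1: enumerate the single baseline value instead
        null_u = len(pooled) - ranks  # U of "a" when element i plays "b"
        u_obs = float(len(pooled) - ranks[-1])
    eps = 1e-9
    p_greater = float(np.mean(null_u >= u_obs - eps))
    if alternative == "greater":
        return p_greater
    p_less = float(np.mean(null_u <= u_obs + eps))
    return min(1.0, 2.0 * min(p_greater, p_less))


def mann_whitney_u(
    a,
    b,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mann-Whitney U test of sample ``a`` against baseline ``b``.

    Returns ``(U, p)`` with U the statistic of ``a``.  For small problems
    (n+m <= 20) the p-value comes from the exact permutation distribution of
    U over all rank assignments (ties handled by construction); larger
    problems use the tie-corrected, continuity-corrected normal
    approximation.  A fully degenerate pooled sample (all values identical)
    yields p = 1 with a warning, never an exception.
    """
    if alternative not in ("greater", "two_sided"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise ParameterError("both samples must be non-empty")
    u = float(_u_statistic(a, b))
    if np.ptp(np.concatenate([a, b])) == 0.0:
        warnings.warn(
            "degenerate baseline: all pooled values identical; p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return u, 1.0
    scipy_alt = "two-sided" if alternative == "two_sided" else "greater"
    if m + n <= EXACT_MAX_N:
        if min(m, n) == 1:
            return u, _exact_p_single(a, b, alternative)
        res = stats.permutation_test(
            (a, b),
            _u_statistic,
            permutation_type="independent",
            alternative=scipy_alt,
            n_resamples=np.inf,
            vectorized=True,
        )
        return u, float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative=scipy_alt, method="asymptotic")
    return u, float(res.pvalue)


@dataclass
class EnrichmentMap:
    """Per-position, per-class enrichment results for one sequence set.

    ``enriched_raw`` holds the pre-filter significance calls (p < alpha);
    the ``enriched`` property masks them with the per-position ``retained``
    flags from the information filter.  A position is *significant* when any
    class is enriched and the position is retained.
    """

    query: str
    scheme: ChemClassScheme
    U: np.ndarray              # (L, K)
    p: np.ndarray              # (L, K)
    enriched_raw: np.ndarray   # (L, K) bool
    info: np.ndarray           # (L,) bits
    diff_norm: np.ndarray      # (L,)
    alpha: float
    sample_mode: str
    alternative: str
    keep_fraction: float = 1.0
    retained: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones(self.L, dtype=bool)

    @property
    def L(self) -> int:
        return len(self.query)

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.scheme.class_names

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.L + 1)

    @property
    def filter_score(self) -> np.ndarray:
        """s_i = I_i * ||d_i||, the ranking score of the position filter."""
        return self.info * self.diff_norm

    @property
    def enriched(self) -> np.ndarray:
        """(L, K) post-filter enrichment flags."""
        return self.enriched_raw & self.retained[:, None]

    @property
    def position_significant(self) -> np.ndarray:
        """(L,) — any class enriched AND position retained."""
        return self.enriched.any(axis=1)

    def enriched_classes(self, i: int) -> frozenset[str]:
        """Class names enriched at 1-based position ``i`` (post-filter)."""
        row = self.enriched[i - 1]
        return frozenset(c for c, flag in zip(self.class_names, row) if flag)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(position, class) table with the per-position filter
        columns repeated on each row."""
        L, K = self.p.shape
        return pd.DataFrame(
            {
                "position": np.repeat(self.positions, K),
                "residue": np.repeat(list(self.query), K),
                "class": list(self.class_names) * L,
                "U": self.U.ravel(),
                "p": self.p.ravel(),
                "enriched": self.enriched.ravel(),
                "info_bits": np.repeat(self.info, K),
                "diff_norm": np.repeat(self.diff_norm, K),
                "filter_score": np.repeat(self.filter_score, K),
                "retained": np.repeat(self.retained, K),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def differential_norms(
    pssm: PSSM, scheme: ChemClassScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position class-vector deviations from the protein baseline.

    The baseline class vector is the mean over all positions of the class
    frequencies; returns ``(d, norms)`` where ``d[i] = F_i - mean_j F_j``
    and ``norms[i]`` is its Euclidean norm.  Since both F_i and the mean lie
    on the probability simplex, norms never exceed sqrt(2).
    """
    F = class_frequencies(pssm, scheme)
    d = F - F.mean(axis=0, keepdims=True)
    return d, np.linalg.norm(d, axis=1)


def test_enrichment(
    pssm: PSSM,
    scheme: ChemClassScheme | None = None,
    alpha: float = 0.01,
    sample_mode: str = "member",
    alternative: str = "greater",
    bh_correct: bool = False,
) -> EnrichmentMap:
    """Test every (position, class) pair for enrichment over the baseline.

    Parameters
    ----------
    alpha
        Raw significance level (default 0.01).
    sample_mode
        ``member`` (default): member frequencies vs the leave-one-out pool
        of member frequencies at all other positions.  ``class_sum``: the
        summed class frequency vs the other positions' sums.
    alternative
        ``greater`` (enrichment, default) or ``two_sided``.
    bh_correct
        Apply Benjamini-Hochberg across all L*K p-values before flagging.

    Raises
    ------
    ParameterError
        If L < 5 (the leave-one-out baseline would be degenerate) or alpha
        is outside (0, 1).
    """
    from .chem import default_scheme

    scheme = scheme or default_scheme()
    if pssm.length < 5:
        raise ParameterError(
            f"need at least 5 positions for a meaningful baseline, got {pssm.length}"
        )
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if sample_mode not in ("member", "class_sum"):
        raise ParameterError(f"unknown sample_mode {sample_mode!r}")

    L = pssm.length
    K = scheme.n_classes
    F = class_frequencies(pssm, scheme)
    U = np.empty((L, K))
    P = np.empty((L, K))
    member_idx = [
        [i for i, aa in enumerate("ARNDCQEGHILKMFPSTWYV") if aa in members]
        for _, members in scheme.classes
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in range(K):
            vals = pssm.freq[:, member_idx[k]] if sample_mode == "member" else F[:, [k]]
            for i in range(L):
                a = vals[i]
                b = np.delete(vals, i, axis=0).ravel()
                U[i, k], P[i, k] = mann_whitney_u(a, b, alternative=alternative)

    if bh_correct:
        flat = P.ravel()
        order = np.argsort(flat)
        ranked = flat[order] * len(flat) / (np.arange(len(flat)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        padj = np.empty_like(flat)
        padj[order] = np.minimum(adj, 1.0)
        flagged = (padj < alpha).reshape(P.shape)
    else:
        flagged = P < alpha

    d, norms = differential_norms(pssm, scheme)
    return EnrichmentMap(
        query=pssm.query,
        scheme=scheme,
        U=U,
        p=P,
        enriched_raw=flagged,
        info=pssm.info.copy(),
        diff_norm=norms,
        alpha=alpha,
        sample_mode=sample_mode,
        alternative=alternative,
        metadata={
            "info_source": pssm.metadata.get("source", "unknown"),
            "bh_correct": bh_correct,
            "exact_max_n": EXACT_MAX_N,
            "tie_break": "position index ascending",
        },
    )


def apply_information_filter(
    emap: EnrichmentMap, keep_fraction: float
) -> EnrichmentMap:
    """Retain the top ``ceil(keep_fraction * L)`` positions by filter score.

    Ranking is by s_i = I_i * ||d_i|| descending, ties broken by position
    index ascending (so retained sets nest as keep_fraction grows).
    Enrichment flags on non-retained positions are revoked via the
    ``retained`` mask; the raw flags stay recorded.
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ParameterError(
            f"keep_fraction must be in [0, 1], got {keep_fraction}"
        )
    L = emap.L
    n_keep = math.ceil(keep_fraction * L)
    s = emap.filter_score
    order = np.lexsort((np.arange(L), -s))  # primary: -s, secondary: position
    retained = np.zeros(L, dtype=bool)
    retained[order[:n_keep]] = True
    return replace(emap, keep_fraction=keep_fraction, retained=retained)
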