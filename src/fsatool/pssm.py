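"""Position-specific scoring matrices: file I/O and construction from MSAs.

A :class:`PSSM` holds, for each position of a query/reference sequence, a
relative-frequency vector over the 20 amino acids, a log-odds vector against
a background distribution, and the position's information content

    I_i = log2(20) - H(p_i)        [bits]

where ``H`` is the Shannon entropy of the frequency row.  Positions are
1-based and anchored to the query, matching the psiblast ASCII dialect; MSA
columns that are gapped in the reference are discarded so that file-derived
and alignment-derived PSSMs share one coordinate system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AA_INDEX, AA_ORDER, GAP, UNKNOWN, Alignment
from .errors import (
    EmptyInputError,
    PssmFormatError,
    PssmParseError,
    UndefinedColumnError,
)

MAX_INFO_BITS = math.log2(20.0)

#: Average Swiss-Prot amino-acid composition (release-stable to ~0.1%),
#: in the canonical column order. A realistic alternative to the uniform
#: background for log-odds and for synthetic alignments.
PROTEIN_BACKGROUND = np.array(
    [
        0.0825, 0.0553, 0.0406, 0.0546, 0.0138, 0.0393, 0.0672, 0.0707,
        0.0227, 0.0591, 0.0965, 0.0580, 0.0241, 0.0386, 0.0474, 0.0665,
        0.0536, 0.0110, 0.0292, 0.0686,
    ]
)
PROTEIN_BACKGROUND = PROTEIN_BACKGROUND / PROTEIN_BACKGROUND.sum()


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def information_content(freq: np.ndarray) -> np.ndarray:
    """Per-row information content in bits: log2(20) minus Shannon entropy.

    Accepts a single frequency vector or an (L, 20) matrix; zero entries
    contribute nothing to the entropy.
    """
    f = np.atleast_2d(np.asarray(freq, dtype=float))
    logf = np.log2(f, out=np.zeros_like(f), where=f > 0)
    ent = -(f * logf).sum(axis=1)
    out = MAX_INFO_BITS - ent
    return out if np.ndim(freq) > 1 else float(out[0])


@dataclass
class PSSM:
    """Query-anchored per-position amino-acid statistics.

    Attributes
    ----------
    query
        Query/reference residues, one per position (length L).
    freq
        (L, 20) relative frequencies in the canonical column order
        (``ARNDCQEGHILKMFPSTWYV``); rows sum to 1.
    logodds
        (L, 20) log-odds scores; units recorded in ``metadata['score_units']``.
    info
        Length-L per-position information content, bits.
    n_effective
        Number of sequences contributing (None when read from a file that
        does not record it).
    """

    query: str
    freq: np.ndarray
    logodds: np.ndarray
    info: np.ndarray
    n_effective: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.info = np.asarray(self.info, dtype=float)
        L = len(self.query)
        if self.freq.shape != (L, 20) or self.logodds.shape != (L, 20):
            raise ValueError("freq and logodds must have shape (L, 20)")
        if self.info.shape != (L,):
            raise ValueError("info must have shape (L,)")
        sums = self.freq.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"frequency row {bad + 1} sums to {sums[bad]:.8f}, expected 1"
            )

    @property
    def length(self) -> int:
        return len(self.query)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.length + 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=list(AA_ORDER))
        df.insert(0, "residue", list(self.query))
        df.insert(0, "position", self.positions)
        df["info"] = self.info
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# psiblast ASCII dialect
# ---------------------------------------------------------------------------

_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


def read_psiblast_pssm(path: str | Path) -> PSSM:
    """Read an ASCII PSSM in the psiblast output dialect.

    The body carries two 20-column blocks per position (log-odds, then
    weighted observed percentages), followed by the per-position information
    content and relative weight.  Percentages are divided by 100; rows whose
    percentages do not sum to 100 (psiblast rounds down) are renormalized
    and the affected positions recorded in ``metadata['renormalized_rows']``.

    Raises
    ------
    PssmFormatError
        Missing column header, missing percentage block, or no data rows.
    PssmParseError
        A non-numeric cell (reports the line number).
    """
    lines = Path(path).read_text().splitlines()
    col_order: list[str] | None = None
    header_line = None
    for lineno, line in enumerate(lines):
        toks = line.split()
        if len(toks) in (20, 40) and all(t in AA_INDEX for t in toks):
            col_order = toks[:20]
            if len(toks) == 20:
                # some writers emit the 20 letters once for both blocks
                col_order = toks
            header_line = lineno
            break
    if col_order is None:
        raise PssmFormatError(f"{path}: no amino-acid column header found")

    query: list[str] = []
    logodds_rows: list[list[float]] = []
    pct_rows: list[list[float]] = []
    info: list[float] = []
    weights: list[float] = []
    expected_pos = 0
    for lineno in range(header_line + 1, len(lines)):
        toks = lines[lineno].split()
        if not toks:
            if query:
                break
            continue
        if not toks[0].isdigit():
            break  # footer (Lambda/K table)
        expected_pos += 1
        if len(toks) < 2 or toks[1] not in AA_INDEX:
            raise PssmFormatError(
                f"{path}:{lineno + 1}: malformed data row"
            )
        numbers = toks[2:]
        if len(numbers) < 41:
            raise PssmFormatError(
                f"{path}:{lineno + 1}: expected log-odds and percentage "
                f"blocks plus information column, found {len(numbers)} fields"
            )
        try:
            vals = [float(x) for x in numbers]
        except ValueError as exc:
            raise PssmParseError(
                f"{path}:{lineno + 1}: non-numeric cell ({exc})"
            ) from None
        query.append(toks[1])
        logodds_rows.append(vals[0:20])
        pct_rows.append(vals[20:40])
        info.append(vals[40])
        weights.append(vals[41] if len(vals) > 41 else float("nan"))

    if not query:
        raise PssmFormatError(f"{path}: truncated file, no PSSM rows")

    # reorder columns into the canonical order
    perm = [col_order.index(a) for a in AA_ORDER]
    logodds = np.array(logodds_rows)[:, perm]
    pct = np.array(pct_rows)[:, perm]
    freq = pct / 100.0
    sums = freq.sum(axis=1)
    renorm = np.where(np.abs(sums - 1.0) > 1e-6)[0]
    if renorm.size:
        ok = sums > 0
        if not ok.all():
            bad = int(np.argmin(ok)) + 1
            raise PssmFormatError(
                f"{path}: percentage row for position {bad} sums to zero"
            )
        freq = freq / sums[:, None]
    return PSSM(
        query="".join(query),
        freq=freq,
        logodds=logodds,
        info=np.array(info),
        metadata={
            "source": str(path),
            "score_units": "half-bits (psiblast dialect)",
            "renormalized_rows": (renorm + 1).tolist(),
            "relative_weights": weights,
        },
    )


def write_psiblast_pssm(pssm: PSSM, path: str | Path, fmt: str = "%.6g") -> None:
    """Write a PSSM in the psiblast ASCII dialect.

    Numbers are written with ``fmt`` (default 6 significant digits), which
    round-trips the integer-valued cells of psiblast files exactly.
    """
    weights = pssm.metadata.get("relative_weights") or [0.0] * pssm.length
    with open(path, "w") as fh:
        fh.write("\n" + _HEADER + "\n")
        letters = "  ".join(AA_ORDER)
        fh.write("            " + letters + "   " + letters + "\n")
        for i in range(pssm.length):
            lo = " ".join(fmt % v for v in pssm.logodds[i])
            pc = " ".join(fmt % v for v in pssm.freq[i] * 100.0)
            w = weights[i] if not math.isnan(weights[i] or 0.0) else 0.0
            fh.write(
                f"{i + 1:5d} {pssm.query[i]}  {lo}  {pc}  "
                + (fmt % pssm.info[i])
                + "  "
                + (fmt % w)
                + "\n"
            )
        fh.write("\n")


# ---------------------------------------------------------------------------
# PSSM from alignment
# ---------------------------------------------------------------------------


def pssm_from_alignment(
    aln: Alignment,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> PSSM:
    """Build a PSSM from an alignment, anchored to its reference sequence.

    Columns gapped in the reference are dropped.  At each remaining column,
    frequencies use only non-gap, non-X characters (their count is ``n_i``):

        p_i(a) = (count_i(a) + pseudocount * background_a) / (n_i + pseudocount)

    Log-odds are ``log2(p_i(a) / background_a)`` (bits) and information
    content is ``log2(20) - H(p_i)``.

    Columns whose gap fraction exceeds ``max_gap_fraction`` are flagged in
    ``metadata['low_coverage_positions']`` but still computed.

    Raises
    ------
    UndefinedColumnError
        If a retained column has zero usable characters (lists positions).
    ParameterError-like ValueError for invalid pseudocount/background.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = uniform_background() if background is None else np.asarray(background, float)
    if bg.shape != (20,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be a 20-vector summing to 1")

    mat = np.array([list(s) for s in aln.seqs])
    ref = np.array(list(aln.reference))
    keep = ref != GAP
    if not keep.any():
        raise EmptyInputError("reference sequence is entirely gapped")
    cols = mat[:, keep]
    query = "".join(ref[keep])
    L = cols.shape[1]

    counts = np.zeros((L, 20))
    n_usable = np.zeros(L)
    gap_frac = np.zeros(L)
    for j in range(L):
        col = cols[:, j]
        usable = (col != GAP) & (col != UNKNOWN)
        n_usable[j] = usable.sum()
        gap_frac[j] = 1.0 - usable.mean()
        if n_usable[j]:
            idx = np.fromiter((AA_INDEX[c] for c in col[usable]), dtype=int)
            counts[j] = np.bincount(idx, minlength=20)

    dead = np.where(n_usable == 0)[0]
    if dead.size:
        raise UndefinedColumnError(
            "no usable characters at position(s) "
            + ", ".join(str(p + 1) for p in dead)
        )

    freq = (counts + pseudocount * bg) / (n_usable + pseudocount)[:, None]
    with np.errstate(divide="ignore"):
        logodds = np.where(freq > 0, np.log2(np.maximum(freq, 1e-300) / bg), -np.inf)
    info = information_content(freq)
    low_cov = (np.where(gap_frac > max_gap_fraction)[0] + 1).tolist()
    return PSSM(
        query=query,
        freq=freq,
        logodds=logodds,
        info=np.asarray(info),
        n_effective=aln.nseq,
        metadata={
            "source": "alignment",
            "score_units": "bits",
            "pseudocount": pseudocount,
            "background": bg.tolist(),
            "low_coverage_positions": low_cov,
        },
    )
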