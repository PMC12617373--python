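"""Multiple sequence alignment container and FASTA readers.

Alignments are rectangular blocks of equal-length amino-acid strings over
the alphabet of the 20 standard residues plus ``-`` (gap) and ``X``
(unknown).  One row is designated the *reference*: all downstream position
coordinates are 1-based indices into the reference's non-gap residues, which
keeps alignment-derived matrices directly comparable to query-anchored PSSM
files.

Two FASTA dialects are supported: plain aligned FASTA, and the ProteinMPNN
output dialect in which each record may hold several chains joined by ``/``
and headers carry sampling metadata (temperature, score, sequence recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AlignmentWidthError, AlphabetError, EmptyInputError

#: Canonical amino-acid order used for every 20-column matrix in the
#: package.  This is the column order of the psiblast ASCII PSSM dialect.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
GAP = "-"
UNKNOWN = "X"
ALPHABET = frozenset(AA_ORDER) | {GAP, UNKNOWN}


def _normalize(seq: str) -> str:
    """Upper-case a sequence and map ``.`` gaps to ``-``."""
    return seq.upper().replace(".", GAP)


@dataclass(frozen=True)
class Alignment:
    """A rectangular multiple sequence alignment.

    Parameters
    ----------
    ids
        One identifier per row.
    seqs
        Equal-length residue strings (upper case, ``-`` for gaps, ``X`` for
        unknown residues).
    reference_index
        Row whose non-gap residues anchor all position coordinates.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have the same length")
        if not self.seqs:
            raise EmptyInputError("alignment contains no sequences")
        width = len(self.seqs[0])
        for rid, s in zip(self.ids, self.seqs):
            if len(s) != width:
                raise AlignmentWidthError(
                    f"record {rid!r} has length {len(s)}, expected {width}"
                )
            for col, ch in enumerate(s):
                if ch not in ALPHABET:
                    raise AlphabetError(
                        f"record {rid!r} has illegal character {ch!r} "
                        f"at column {col + 1}"
                    )
        if not 0 <= self.reference_index < len(self.seqs):
            raise ValueError(
                f"reference_index {self.reference_index} out of range "
                f"for {len(self.seqs)} sequences"
            )

    @property
    def width(self) -> int:
        return len(self.seqs[0])

    @property
    def nseq(self) -> int:
        return len(self.seqs)

    @property
    def reference(self) -> str:
        return self.seqs[self.reference_index]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str]], reference_index: int = 0
    ) -> "Alignment":
        ids, seqs = [], []
        for rid, s in records:
            ids.append(rid)
            seqs.append(_normalize(s))
        if not seqs:
            raise EmptyInputError("no records supplied")
        return cls(tuple(ids), tuple(seqs), reference_index)


@dataclass(frozen=True)
class MpnnDialectOptions:
    """How to interpret ProteinMPNN-style multi-chain FASTA records.

    ``chain_policy`` is one of:

    - ``first_chain``: keep only the first chain of every record (default;
      sensible for homodimer designs where protomers are near-copies),
    - ``concatenate``: join all chains of a record into one row,
    - ``pool_all_chains``: emit each chain as an independent row.
    """

    chain_separator: str = "/"
    chain_policy: str = "first_chain"
    drop_header_metadata: bool = True

    _POLICIES = ("first_chain", "concatenate", "pool_all_chains")

    def __post_init__(self) -> None:
        if self.chain_policy not in self._POLICIES:
            raise ValueError(
                f"chain_policy must be one of {self._POLICIES}, "
                f"got {self.chain_policy!r}"
            )


def read_msa(path: str | Path, reference_index: int = 0) -> Alignment:
    """Read a plain aligned FASTA file.

    Raises
    ------
    EmptyInputError
        If the file holds no FASTA records.
    AlignmentWidthError
        If records are ragged (names the offending record).
    AlphabetError
        If a record contains a character outside the alphabet.
    """
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Alignment.from_records(records, reference_index)


def read_mpnn_fasta(
    path: str | Path,
    opts: MpnnDialectOptions | None = None,
    reference_index: int = 0,
) -> Alignment:
    """Read a ProteinMPNN output FASTA file into an alignment.

    Design outputs are ungapped and share the backbone's length, so the
    rows form a trivial alignment.  Multi-chain records are handled per
    ``opts.chain_policy``.
    """
    opts = opts or MpnnDialectOptions()
    rows: list[tuple[str, str]] = []
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise EmptyInputError(f"no FASTA records in {path}")
    for rec in parsed:
        rid = rec.id.split(",")[0] if opts.drop_header_metadata else rec.description
        chains = _normalize(str(rec.seq)).split(opts.chain_separator)
        if opts.chain_policy == "first_chain":
            rows.append((rid, chains[0]))
        elif opts.chain_policy == "concatenate":
            rows.append((rid, "".join(chains)))
        else:  # pool_all_chains
            for k, chain in enumerate(chains, start=1):
                rows.append((f"{rid}/{k}", chain))
    return Alignment.from_records(rows, reference_index)


def write_msa(aln: Alignment, path: str | Path, wrap: int = 60) -> None:
    """Write an alignment as plain FASTA."""
    with open(path, "w") as fh:
        for rid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
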