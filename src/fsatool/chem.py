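"""Physicochemical grouping of the 20 amino acids.

The enrichment statistics operate on classes of chemically similar residues
rather than on single amino acids, so that e.g. a position conserving either
histidine or glutamine still registers as a conserved *polar* position.  The
default partition has six classes: acidic, basic, hydrophilic (polar),
hydrophobic, and the two conformationally special singletons glycine and
proline.  Any user-defined partition of the 20 residues is accepted; class
order is fixed at construction so per-position class vectors are comparable
across runs.

Histidine sits in the hydrophilic class by default (its charge state is
pH-dependent); cysteine and tyrosine are likewise grouped as polar and
tryptophan as hydrophobic.  Single-scheme hard assignments are inevitably a
simplification for such residues, which is why the scheme is an explicit,
overridable configuration object recorded in all output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .alignment import AA_INDEX, AA_ORDER
from .errors import SchemeError
from .pssm import PSSM

_DEFAULT_CLASSES = (
    ("acidic", "DE"),
    ("basic", "KR"),
    ("hydrophilic", "STNQHCY"),
    ("hydrophobic", "AVLIMFW"),
    ("glycine", "G"),
    ("proline", "P"),
)


@dataclass(frozen=True)
class ChemClassScheme:
    """An ordered partition of the 20 amino acids into named classes."""

    name: str
    classes: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cname, members in self.classes:
            if not members:
                raise SchemeError(f"class {cname!r} is empty")
            for aa in members:
                if aa not in AA_INDEX:
                    raise SchemeError(
                        f"class {cname!r} contains unknown residue {aa!r}"
                    )
                if aa in seen:
                    raise SchemeError(
                        f"residue {aa!r} appears in more than one class"
                    )
                seen.add(aa)
        missing = set(AA_ORDER) - seen
        if missing:
            raise SchemeError(
                "scheme does not cover residues: " + "".join(sorted(missing))
            )

    @classmethod
    def from_dict(
        cls, classes: Mapping[str, str] | Sequence[tuple[str, str]], name: str = "custom"
    ) -> "ChemClassScheme":
        items = classes.items() if isinstance(classes, Mapping) else classes
        return cls(
            name=name,
            classes=tuple(
                (cname, frozenset(members.upper())) for cname, members in items
            ),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChemClassScheme":
        data = yaml.safe_load(Path(path).read_text())
        name = data.pop("name", Path(path).stem) if isinstance(data, dict) else "custom"
        return cls.from_dict(data, name=name)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(cname for cname, _ in self.classes)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def members(self, class_name: str) -> frozenset[str]:
        for cname, m in self.classes:
            if cname == class_name:
                return m
        raise KeyError(class_name)

    def lookup(self, aa: str) -> str:
        """Return the class name of a one-letter amino-acid code."""
        aa = aa.upper()
        for cname, m in self.classes:
            if aa in m:
                return cname
        raise KeyError(f"unknown amino acid {aa!r}")

    def membership_matrix(self) -> np.ndarray:
        """(20, K) 0/1 matrix mapping amino-acid columns to classes."""
        M = np.zeros((20, self.n_classes))
        for k, (_, members) in enumerate(self.classes):
            for aa in members:
                M[AA_INDEX[aa], k] = 1.0
        return M

    def to_dict(self) -> dict[str, str]:
        return {cname: "".join(sorted(m)) for cname, m in self.classes}


def default_scheme() -> ChemClassScheme:
    """The six-class default partition.

    acidic {D,E}; basic {K,R}; hydrophilic {S,T,N,Q,H,C,Y};
    hydrophobic {A,V,L,I,M,F,W}; glycine {G}; proline {P}.
    """
    return ChemClassScheme.from_dict(_DEFAULT_CLASSES, name="default-6")


def class_frequencies(pssm: PSSM, scheme: ChemClassScheme) -> np.ndarray:
    """(L, K) matrix of per-position class frequencies F_i(c).

    F_i(c) is the summed frequency of the class members at position i; rows
    sum to 1 because the scheme is a partition.
    """
    return pssm.freq @ scheme.membership_matrix()
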