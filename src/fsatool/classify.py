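"""Combine natural- and design-derived enrichment maps into FSA labels.

The per-position truth table:

=====================  =====================  ============
natural significant    designed significant   label
=====================  =====================  ============
yes                    no                     functional
no                     yes                    adaptable
yes                    yes                    structural
no                     no                     unlabeled
=====================  =====================  ============

"Significant" means at least one chemical class enriched and the position
retained by the information filter.  In ``same_class`` convergence mode the
structural call additionally requires at least one class enriched in *both*
sets; doubly-significant positions with disjoint class sets then stay
unlabeled (with both class sets kept in the provenance columns).

Positions whose natural enrichment does not include the query residue's own
class are additionally flagged ``query_deviates``: the alignment conserves a
chemistry the query itself does not carry, a biologically informative
special case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import EnrichmentMap
from .errors import IncompatibleInputsError, KeyRangeError

LABELS = ("functional", "structural", "adaptable", "unlabeled")


@dataclass(frozen=True)
class KeyResidueList:
    """Literature-described key residues for benchmarking label capture."""

    entries: tuple[tuple[int, str], ...]
    source: str = ""

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeyResidueList":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return cls(
            entries=tuple((int(r[0]), str(r[1])) for r in df.itertuples(index=False)),
            source=str(path),
        )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.entries)


@dataclass
class AnnotationTrack:
    """Final per-position FSA annotation with provenance."""

    labels: tuple[str, ...]
    query: str
    natural_classes: tuple[frozenset[str], ...]
    designed_classes: tuple[frozenset[str], ...]
    query_deviates: tuple[bool, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return len(self.labels)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.L + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "residue": list(self.query),
                "label": self.labels,
                "natural_classes": [
                    ",".join(sorted(c)) for c in self.natural_classes
                ],
                "designed_classes": [
                    ",".join(sorted(c)) for c in self.designed_classes
                ],
                "query_deviates": self.query_deviates,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify(
    natural: EnrichmentMap,
    designed: EnrichmentMap,
    convergence_mode: str = "any",
) -> AnnotationTrack:
    """Assign an FSA label to every position from two enrichment maps.

    Raises
    ------
    IncompatibleInputsError
        When the maps differ in length or chemical-class scheme.
    """
    if natural.L != designed.L:
        raise IncompatibleInputsError(
            f"length mismatch: natural has {natural.L} positions, "
            f"designed has {designed.L}"
        )
    if natural.scheme.classes != designed.scheme.classes:
        raise IncompatibleInputsError("the two maps use different class schemes")
    if convergence_mode not in ("any", "same_class"):
        raise IncompatibleInputsError(
            f"unknown convergence_mode {convergence_mode!r}"
        )

    scheme = natural.scheme
    nat_sig = natural.position_significant
    des_sig = designed.position_significant
    labels: list[str] = []
    nat_classes: list[frozenset[str]] = []
    des_classes: list[frozenset[str]] = []
    deviates: list[bool] = []
    for i in range(natural.L):
        nc = natural.enriched_classes(i + 1)
        dc = designed.enriched_classes(i + 1)
        if nat_sig[i] and des_sig[i]:
            if convergence_mode == "same_class" and not (nc & dc):
                label = "unlabeled"
            else:
                label = "structural"
        elif nat_sig[i]:
            label = "functional"
        elif des_sig[i]:
            label = "adaptable"
        else:
            label = "unlabeled"
        labels.append(label)
        nat_classes.append(nc)
        des_classes.append(dc)
        q = natural.query[i]
        deviates.append(bool(nc) and (q == "X" or scheme.lookup(q) not in nc))

    return AnnotationTrack(
        labels=tuple(labels),
        query=natural.query,
        natural_classes=tuple(nat_classes),
        designed_classes=tuple(des_classes),
        query_deviates=tuple(deviates),
        metadata={
            "scheme": scheme.name,
            "scheme_classes": scheme.to_dict(),
            "alpha": natural.alpha,
            "keep_fraction_natural": natural.keep_fraction,
            "keep_fraction_designed": designed.keep_fraction,
            "sample_mode": natural.sample_mode,
            "alternative": natural.alternative,
            "convergence_mode": convergence_mode,
        },
    )


def summarize_fractions(track: AnnotationTrack) -> dict[str, float]:
    """Percentage of positions carrying each label (sums to 100)."""
    counts = pd.Series(track.labels).value_counts()
    return {
        label: float(100.0 * counts.get(label, 0) / track.L) for label in LABELS
    }


def composition_by_class(track: AnnotationTrack) -> dict[str, dict]:
    """Amino-acid composition of the query residues within each label.

    Returns per label: total count, per-residue counts, and per-residue
    percentages of that label's total.
    """
    out: dict[str, dict] = {}
    residues = np.array(list(track.query))
    labels = np.array(track.labels)
    for label in LABELS:
        subset = residues[labels == label]
        total = len(subset)
        counts = pd.Series(subset).value_counts().to_dict() if total else {}
        out[label] = {
            "total": total,
            "counts": {str(k): int(v) for k, v in counts.items()},
            "percentages": {
                str(k): 100.0 * v / total for k, v in counts.items()
            },
        }
    return out


def capture_stats(track: AnnotationTrack, keys: KeyResidueList) -> dict[str, int]:
    """Count the FSA labels assigned to a list of key residues.

    Raises
    ------
    KeyRangeError
        If a key position lies outside [1, L] (names the key).
    """
    counts = {f"n_{label}": 0 for label in LABELS}
    for pos, name in keys.entries:
        if not 1 <= pos <= track.L:
            raise KeyRangeError(
                f"key residue {name!r} at position {pos} is outside [1, {track.L}]"
            )
        counts[f"n_{track.labels[pos - 1]}"] += 1
    counts["n_keys"] = len(keys.entries)
    return counts


def summary_json(
    track: AnnotationTrack,
    keys: KeyResidueList | None = None,
    extra: dict | None = None,
) -> dict:
    """Full machine-readable run summary (fractions, compositions, params)."""
    payload = {
        "n_positions": track.L,
        "label_fractions_pct": summarize_fractions(track),
        "composition_by_label": composition_by_class(track),
        "parameters": track.metadata,
    }
    if keys is not None:
        payload["key_residue_capture"] = capture_stats(track, keys)
    if extra:
        payload.update(extra)
    return payload


def write_summary_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
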