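"""Synthetic paired alignments with planted, ground-truth-labeled enrichment.

The generator emulates the statistical structure the classifier assumes:
two independent sequence sets (an "evolutionary" and a "designed" one) whose
columns are i.i.d. draws from a background distribution, except at *planted*
positions where, with probability ``strength``, the residue is drawn
uniformly from a chosen chemical class.  Planting a position in the natural
set only makes its expected label ``functional``; in the designed set only,
``adaptable``; in both, ``structural``.

A shared reference sequence (the per-column modal residue of the natural
draws) is prepended to both alignments, mirroring real inputs where the
design run is conditioned on the natural query's backbone.

Real data differ in ways the generator deliberately ignores: natural
homologs are phylogenetically correlated and designed sequences are
correlated through the backbone, whereas all rows here are independent.
The column-level statistics the pipeline consumes are unaffected by this
simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import AA_INDEX, AA_ORDER, Alignment
from .chem import ChemClassScheme, default_scheme
from .classify import LABELS, AnnotationTrack
from .errors import ParameterError
from .pssm import PROTEIN_BACKGROUND, uniform_background

_SET_TO_LABEL = {"natural": "functional", "designed": "adaptable", "both": "structural"}


@dataclass(frozen=True)
class Plant:
    """One planted enrichment: ``planted_set`` is natural/designed/both."""

    position: int
    target_class: str
    planted_set: str
    strength: float = 0.9

    def __post_init__(self) -> None:
        if self.planted_set not in _SET_TO_LABEL:
            raise ParameterError(f"unknown planted_set {self.planted_set!r}")
        if not 0.0 < self.strength <= 1.0:
            raise ParameterError("strength must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic paired-alignment draw."""

    L: int = 120
    n_natural: int = 200
    n_designed: int = 200
    background: tuple[float, ...] | None = None  # None = uniform
    planted: tuple[Plant, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_natural < 2 or self.n_designed < 2:
            raise ParameterError("need at least 2 sequences per set")
        positions = [p.position for p in self.planted]
        if len(set(positions)) != len(positions):
            raise ParameterError("planted positions must be unique")
        for p in self.planted:
            if not 1 <= p.position <= self.L:
                raise ParameterError(
                    f"planted position {p.position} outside [1, {self.L}]"
                )


@dataclass(frozen=True)
class TruthTrack:
    """Expected label per position, implied by the planted sites."""

    labels: tuple[str, ...]

    @classmethod
    def from_spec(cls, spec: SyntheticSpec) -> "TruthTrack":
        labels = ["unlabeled"] * spec.L
        for p in spec.planted:
            labels[p.position - 1] = _SET_TO_LABEL[p.planted_set]
        return cls(tuple(labels))


def study_spec(
    seed: int = 0,
    L: int = 120,
    n_natural: int = 200,
    n_designed: int = 200,
    strength: float = 0.9,
    per_label: int = 10,
    target_classes: Sequence[str] = ("hydrophilic", "hydrophobic"),
) -> SyntheticSpec:
    """The benchmark conditions: L=120, 200 sequences per set, planting
    strength 0.9, ten planted positions per label type.

    Plants alternate between the given target classes (default: the two
    seven-member classes, where the member-mode U test has full power; see
    the methods note on class-size power limits) and are spread evenly
    along the sequence, interleaving the three label types.
    """
    n_plants = 3 * per_label
    positions = np.linspace(1, L, n_plants + 2)[1:-1].round().astype(int)
    positions = np.unique(positions)
    if len(positions) < n_plants:
        raise ParameterError("L too small for the requested number of plants")
    sets = ["natural", "designed", "both"] * per_label
    plants = tuple(
        Plant(
            position=int(pos),
            target_class=target_classes[i % len(target_classes)],
            planted_set=sets[i],
            strength=strength,
        )
        for i, pos in enumerate(positions[:n_plants])
    )
    return SyntheticSpec(
        L=L,
        n_natural=n_natural,
        n_designed=n_designed,
        planted=plants,
        seed=seed,
    )


def _column_probs(
    spec: SyntheticSpec, which: str, scheme: ChemClassScheme
) -> np.ndarray:
    bg = (
        uniform_background()
        if spec.background is None
        else np.asarray(spec.background, float)
    )
    probs = np.tile(bg, (spec.L, 1))
    for p in spec.planted:
        if p.planted_set in (which, "both"):
            members = scheme.members(p.target_class)
            target = np.zeros(20)
            for aa in members:
                target[AA_INDEX[aa]] = 1.0 / len(members)
            probs[p.position - 1] = (
                p.strength * target + (1.0 - p.strength) * bg
            )
    return probs


def simulate_paired_alignments(
    spec: SyntheticSpec, scheme: ChemClassScheme | None = None
) -> tuple[Alignment, Alignment, TruthTrack]:
    """Draw one (natural, designed, truth) triple; pure function of the seed.

    Both alignments carry the shared reference row (id ``query``) at index 0
    followed by ``n_natural`` / ``n_designed`` sampled rows.
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AA_ORDER))

    def draw(probs: np.ndarray, n: int, prefix: str) -> list[str]:
        cols = [rng.choice(20, size=n, p=probs[j]) for j in range(spec.L)]
        mat = np.stack(cols, axis=1)  # (n, L)
        return ["".join(aa[row]) for row in mat]

    nat_rows = draw(_column_probs(spec, "natural", scheme), spec.n_natural, "nat")
    des_rows = draw(_column_probs(spec, "designed", scheme), spec.n_designed, "des")

    # reference: per-column modal residue of the natural draws
    nat_mat = np.array([list(s) for s in nat_rows])
    ref_chars = []
    for j in range(spec.L):
        vals, counts = np.unique(nat_mat[:, j], return_counts=True)
        ref_chars.append(vals[np.argmax(counts)])
    ref = "".join(ref_chars)

    natural = Alignment.from_records(
        [("query", ref)] + [(f"nat_{i:04d}", s) for i, s in enumerate(nat_rows)]
    )
    designed = Alignment.from_records(
        [("query", ref)] + [(f"des_{i:04d}", s) for i, s in enumerate(des_rows)]
    )
    return natural, designed, TruthTrack.from_spec(spec)


def score_recovery(track: AnnotationTrack, truth: TruthTrack) -> dict:
    """Per-label precision/recall of the pipeline against planted truth.

    Precision/recall for labels with no predicted/true positives are
    reported as None.  ``planted_recovery`` is the fraction of planted
    (non-unlabeled-truth) positions that received exactly their true label.
    """
    pred = np.array(track.labels)
    true = np.array(truth.labels)
    out: dict = {}
    for label in LABELS:
        tp = int(((pred == label) & (true == label)).sum())
        npred = int((pred == label).sum())
        ntrue = int((true == label).sum())
        out[f"precision_{label}"] = tp / npred if npred else None
        out[f"recall_{label}"] = tp / ntrue if ntrue else None
    planted = true != "unlabeled"
    out["n_planted"] = int(planted.sum())
    out["planted_recovery"] = (
        float((pred[planted] == true[planted]).mean()) if planted.any() else None
    )
    return out


def sweep_recovery(
    spec_grid: Iterable[SyntheticSpec],
    scheme: ChemClassScheme | None = None,
    **pipeline_params,
) -> pd.DataFrame:
    """Run the full pipeline over a grid of specs; one row per spec with the
    per-label precision/recall and the spec's parameters."""
    from .pipeline import annotate_pair  # deferred: avoids an import cycle

    rows = []
    for spec in spec_grid:
        natural, designed, truth = simulate_paired_alignments(spec, scheme)
        track = annotate_pair(natural, designed, scheme=scheme, **pipeline_params)
        row = {
            "L": spec.L,
            "n_natural": spec.n_natural,
            "n_designed": spec.n_designed,
            "n_planted": len(spec.planted),
            "strength": spec.planted[0].strength if spec.planted else None,
            "seed": spec.seed,
            **{k: v for k, v in pipeline_params.items() if np.isscalar(v)},
        }
        row.update(score_recovery(track, truth))
        rows.append(row)
    return pd.DataFrame(rows)
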