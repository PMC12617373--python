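"""End-to-end runs: configuration, orchestration, and serialized outputs.

``annotate_pair`` is the in-memory core (alignments or PSSMs in, annotation
track out); ``run_pipeline`` wraps it with file I/O, producing an annotation
TSV, a JSON summary echoing every parameter, a heatmap image, and a log.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .alignment import Alignment, MpnnDialectOptions, read_mpnn_fasta, read_msa
from .chem import ChemClassScheme, default_scheme
from .classify import (
    AnnotationTrack,
    KeyResidueList,
    classify,
    summary_json,
    write_summary_json,
)
from .enrichment import apply_information_filter, test_enrichment
from .errors import IncompatibleInputsError, ParameterError
from .pssm import PSSM, pssm_from_alignment, read_psiblast_pssm

logger = logging.getLogger("fsatool")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run.

    Exactly one of (msa, pssm) must be given per branch.  ``designed_msa``
    may be in the ProteinMPNN multi-chain dialect; set ``mpnn_dialect``.
    """

    natural_msa: str | None = None
    natural_pssm: str | None = None
    designed_msa: str | None = None
    designed_pssm: str | None = None
    mpnn_dialect: bool = False
    chain_policy: str = "first_chain"
    alpha: float = 0.01
    keep_fraction: float = 0.8
    sample_mode: str = "member"
    alternative: str = "greater"
    convergence_mode: str = "any"
    scheme_file: str | None = None
    keys: str | None = None
    pseudocount: float = 1.0
    out_prefix: str = "fsa_run"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for branch in ("natural", "designed"):
            msa = getattr(self, f"{branch}_msa")
            pssm = getattr(self, f"{branch}_pssm")
            if (msa is None) == (pssm is None):
                raise ParameterError(
                    f"exactly one of {branch}_msa / {branch}_pssm must be set"
                )


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def annotate_pair(
    natural: Alignment | PSSM,
    designed: Alignment | PSSM,
    scheme: ChemClassScheme | None = None,
    alpha: float = 0.01,
    keep_fraction: float = 0.8,
    sample_mode: str = "member",
    alternative: str = "greater",
    convergence_mode: str = "any",
    pseudocount: float = 1.0,
) -> AnnotationTrack:
    """Run the full statistical pipeline on two in-memory inputs.

    Each branch is tested and filtered independently (the filter is applied
    per set before the two maps are compared), then combined into labels.
    """
    scheme = scheme or default_scheme()
    maps = []
    for obj in (natural, designed):
        pssm = (
            pssm_from_alignment(obj, pseudocount=pseudocount)
            if isinstance(obj, Alignment)
            else obj
        )
        emap = test_enrichment(
            pssm,
            scheme,
            alpha=alpha,
            sample_mode=sample_mode,
            alternative=alternative,
        )
        maps.append(apply_information_filter(emap, keep_fraction))
    if maps[0].L != maps[1].L:
        raise IncompatibleInputsError(
            f"length mismatch between branches: natural has {maps[0].L} "
            f"positions, designed has {maps[1].L}"
        )
    return classify(maps[0], maps[1], convergence_mode=convergence_mode)


def _load_branch(cfg: RunConfig, branch: str) -> Alignment | PSSM:
    msa = getattr(cfg, f"{branch}_msa")
    if msa is not None:
        if branch == "designed" and cfg.mpnn_dialect:
            return read_mpnn_fasta(
                msa, MpnnDialectOptions(chain_policy=cfg.chain_policy)
            )
        return read_msa(msa)
    return read_psiblast_pssm(getattr(cfg, f"{branch}_pssm"))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a configured run and write all outputs.

    Returns a dict with the ``track`` and the paths of the annotation TSV,
    summary JSON, and heatmap image.  Deterministic given the config.
    """
    from .viz import render_heatmap  # deferred: matplotlib import is slow

    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    scheme = (
        ChemClassScheme.from_yaml(cfg.scheme_file) if cfg.scheme_file else None
    )
    natural = _load_branch(cfg, "natural")
    designed = _load_branch(cfg, "designed")
    logger.info("inputs loaded; running enrichment tests")
    track = annotate_pair(
        natural,
        designed,
        scheme=scheme,
        alpha=cfg.alpha,
        keep_fraction=cfg.keep_fraction,
        sample_mode=cfg.sample_mode,
        alternative=cfg.alternative,
        convergence_mode=cfg.convergence_mode,
        pseudocount=cfg.pseudocount,
    )
    digests = {
        name: _digest(p)
        for name, p in (
            ("natural", cfg.natural_msa or cfg.natural_pssm),
            ("designed", cfg.designed_msa or cfg.designed_pssm),
        )
    }
    track.metadata["input_digests"] = digests

    keys = KeyResidueList.from_tsv(cfg.keys) if cfg.keys else None
    prefix = Path(cfg.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_name(prefix.name + "_annotation.tsv")
    js = prefix.with_name(prefix.name + "_summary.json")
    img = prefix.with_name(prefix.name + "_heatmap.png")
    track.to_tsv(tsv)
    payload = summary_json(track, keys=keys, extra={"config": asdict(cfg)})
    write_summary_json(payload, js)
    render_heatmap(track, img)
    logger.info("outputs written with prefix %s", cfg.out_prefix)
    return {"track": track, "annotation": tsv, "summary": js, "heatmap": img}
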