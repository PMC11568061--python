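"""End-to-end screening runs: capture -> filter -> summarize -> tree.

A :class:`PipelineConfig` names the inputs and run constants; `run_screen`
executes the funnel and writes all artifacts plus a manifest. Reruns with
identical config and inputs are byte-identical (no timestamps, all
randomness from the single seed).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from . import anchors as _anchors
from . import io as _io
from . import njtree as _njtree
from . import pairwise as _pairwise
from . import profile_hmm as _hmm
from . import taxa as _taxa
from .errors import ConfigError, MglError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and run constants for one screening run.

    ``hmm_threshold`` defaults to the classic capture cut of 150 bits;
    because the in-repo scorer runs in global mode the useful value
    depends on the model and should be calibrated per dataset (pass
    ``-inf`` to disable gating). Alignment defaults echo the published
    Kalign penalties (BLOSUM62, open 10.0, extend 3.0).
    """

    candidates_fasta: str
    reference_fasta: str
    out_dir: str
    seed_msa: str | None = None
    hmm_profile: str | None = None
    taxonomy_tsv: str | None = None
    annotation_tsv: str | None = None
    hmm_threshold: float = 150.0
    motif1: str = "YGC"
    motif1_start: int = 114
    motif2: str = "KD"
    motif2_start: int = 240
    gap_open: float = 10.0
    gap_extend: float = 3.0
    identity_denominator: str = "columns"
    distance_correction: str = "none"
    rank: str = "phylum"
    position_tolerance: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("candidates_fasta", "reference_fasta", "seed_msa",
                     "hmm_profile", "taxonomy_tsv", "annotation_tsv"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"{name} does not exist: {path}")
        if self.seed_msa and self.hmm_profile:
            raise ConfigError("give either seed_msa or hmm_profile, not both")
        if self.rank not in _taxa.RANKS:
            raise ConfigError(f"unknown rank {self.rank!r}")
        if self.distance_correction not in ("none", "poisson"):
            raise ConfigError(
                f"unknown distance correction {self.distance_correction!r}"
            )
        if not (self.hmm_threshold == float("-inf") or
                self.hmm_threshold == self.hmm_threshold):  # NaN check
            raise ConfigError("hmm_threshold must be finite or -inf")


CONFIG_KEYS = [f.name for f in dataclasses.fields(PipelineConfig)]


def load_config_file(path) -> dict:
    """Flat key=value (or key<TAB>value) config text; '#' starts a comment."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, val = line.split("=", 1)
            elif "\t" in line:
                key, val = line.split("\t", 1)
            else:
                raise ConfigError(f"config line {lineno}: expected key=value")
            key, val = key.strip(), val.strip()
            if key not in CONFIG_KEYS:
                raise ConfigError(f"config line {lineno}: unknown key {key!r}")
            out[key] = val
    return out


def _coerce(config_kwargs: dict) -> dict:
    """String config values -> typed values per the dataclass fields."""
    types = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    out = {}
    for key, val in config_kwargs.items():
        if not isinstance(val, str):
            out[key] = val
            continue
        t = types[key]
        if "float" in str(t):
            out[key] = float(val)
        elif "int" in str(t):
            out[key] = int(val)
        else:
            out[key] = val
    return out


def build_config(file_path=None, **cli_overrides) -> PipelineConfig:
    """Merge defaults < config file < CLI overrides."""
    kwargs = {}
    if file_path:
        kwargs.update(load_config_file(file_path))
    kwargs.update({k: v for k, v in cli_overrides.items() if v is not None})
    return PipelineConfig(**_coerce(kwargs))


def run_screen(config: PipelineConfig) -> dict:
    """Execute the funnel; returns artifact paths, funnel counts, verdicts.

    Any stage error removes files already written in this run and
    re-raises, so a failed run leaves no partial outputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def path_for(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    try:
        records = _io.read_fasta(config.candidates_fasta)
        reference = _io.read_fasta(config.reference_fasta)[0]
        anchor = _anchors.ReferenceAnchor(
            reference=reference,
            motif1=config.motif1,
            motif1_start=config.motif1_start,
            motif2=config.motif2,
            motif2_start=config.motif2_start,
        )
        align_params = {
            "gap_open": config.gap_open,
            "gap_extend": config.gap_extend,
            "identity_denominator": config.identity_denominator,
        }

        hits = None
        if config.seed_msa or config.hmm_profile:
            if config.hmm_profile:
                model = _hmm.read_hmmer3_profile(config.hmm_profile)
            else:
                msa = (
                    _io.read_stockholm(config.seed_msa)
                    if _looks_stockholm(config.seed_msa)
                    else _io.read_aligned_fasta(config.seed_msa)
                )
                model = _hmm.build_from_msa(msa)
            logger.info("scoring %d records against model (M=%d)",
                        len(records), model.length)
            hits = _hmm.screen(model, records, threshold=config.hmm_threshold)
            _io.write_table(
                pd.DataFrame(
                    {
                        "id": [h.id for h in hits],
                        "bit_score": [f"{h.bit_score:.4f}" for h in hits],
                        "passed": [str(h.passed) for h in hits],
                    }
                ),
                path_for("hits.tsv"),
            )

        annotation = (
            _io.read_table(config.annotation_tsv, required_columns=("id", "label"))
            if config.annotation_tsv
            else None
        )
        taxonomy = (
            _io.read_table(config.taxonomy_tsv, required_columns=("id", "lineage"))
            if config.taxonomy_tsv
            else None
        )

        verdicts, funnel = _anchors.screen_batch(
            records,
            anchor,
            align_params=align_params,
            hmm_hits=hits,
            annotation_table=annotation,
            position_tolerance=config.position_tolerance,
        )
        _io.write_table(_anchors.verdicts_to_table(verdicts), path_for("verdicts.tsv"))
        funnel_df = pd.DataFrame(
            [
                {
                    "n_input": funnel.n_input,
                    "n_hmm_pass": funnel.n_hmm_pass,
                    "n_with_ygc": funnel.n_with_ygc,
                    "n_with_ygc_kd": funnel.n_with_ygc_kd,
                    "n_confirmed": funnel.n_confirmed,
                }
            ]
        )
        _io.write_table(funnel_df, path_for("funnel.tsv"))

        confirmed_ids = {
            v.id for v in verdicts if v.status is _anchors.Status.CONFIRMED
        }
        confirmed = [r for r in records if r.id in confirmed_ids]
        if confirmed:
            _io.write_fasta(confirmed, path_for("confirmed.fasta"))

        if taxonomy is not None:
            summaries = _taxa.summarize_by_rank(verdicts, taxonomy, rank=config.rank)
            _io.write_table(
                _taxa.summaries_to_table(summaries), path_for("summary.tsv")
            )
            _taxa.write_itol_annotation(summaries, path_for("itol_annotation.txt"))

        if len(confirmed) >= 2:
            msa = _pairwise.reference_anchored_msa(
                reference,
                confirmed,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
            # drop the reference row: the tree is of confirmed hits only
            hit_msa = _io.Msa(records=msa.records[1:]) if len(msa.records) > 2 else msa
            _io.write_aligned_fasta(msa, path_for("confirmed_aligned.fasta"))
            if len(hit_msa.records) >= 2:
                dm = _njtree.distance_matrix(
                    hit_msa, correction=config.distance_correction
                )
                tree = _njtree.neighbor_joining(dm)
                _njtree.write_newick(tree, path_for("tree.nwk"))

        manifest_rows = [("mglscreen_version", __version__)]
        manifest_rows += [(k, repr(v)) for k, v in asdict(config).items()]
        manifest_rows += [
            ("funnel", f"{funnel.n_input},{funnel.n_hmm_pass},{funnel.n_with_ygc},"
                       f"{funnel.n_with_ygc_kd},{funnel.n_confirmed}")
        ]
        _io.write_table(
            pd.DataFrame(manifest_rows, columns=["key", "value"]),
            path_for("manifest.tsv"),
        )
    except MglError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return {
        "out_dir": str(out_dir),
        "funnel": funnel,
        "verdicts": verdicts,
        "artifacts": [str(p) for p in written],
    }


def _looks_stockholm(path) -> bool:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return first.startswith("# STOCKHOLM")
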