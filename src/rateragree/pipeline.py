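"""End-to-end analysis runs: configuration, outputs, manifest.

A :class:`RunConfig` names the inputs, the requested analyses and the
output directory; :func:`run_full_analysis` executes the analyses and
writes every table twice (TSV for reading, JSON for machines) plus a
manifest recording each output file with a content checksum and the
parameters that produced it, so a run is reproducible and auditable.
All randomness flows from the single top-level seed, fanned out to named
substreams so each stochastic analysis is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import io as rio
from .agreement import render_table1, stratified_opa, table1_report
from .core import HER2_SCHEMA, ScoreMatrix
from .onest import ONESTConfig, onest_curves
from .recode import BUILTIN_RECODES, SubsetSpec, builtin_recode, recode, select_subset, subset_case_cooccurrence, subset_rating_counts
from .simulate import SimConfig, her2_default_config, simulate_panel

logger = logging.getLogger("rateragree")

__all__ = ["RunConfig", "run_full_analysis"]

VALID_ANALYSES = ("table1", "crosstabs", "onest", "stratified", "simulate")
_STOCHASTIC = {"onest", "simulate"}


@dataclass
class RunConfig:
    """One reproducible analysis run."""

    out_dir: Path
    analyses: tuple[str, ...]
    scores_path: Path | None = None
    observer_meta_path: Path | None = None
    case_meta_path: Path | None = None
    transposed: bool = False
    seed: int | None = None
    onest: ONESTConfig | None = None
    onest_recode: str | None = None  # built-in recode name applied before ONEST
    onest_subset: str | None = None  # anchor label for an "X only" subset before ONEST
    sim_config: SimConfig | None = None
    display_digits: int = 2

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.analyses = tuple(self.analyses)
        if not self.analyses:
            raise ValueError("no analyses requested")
        unknown = set(self.analyses) - set(VALID_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; valid: {VALID_ANALYSES}")
        if _STOCHASTIC & set(self.analyses) and self.seed is None:
            raise ValueError("a seed is required for stochastic analyses (onest, simulate)")
        if self.scores_path is None and "simulate" not in self.analyses:
            raise ValueError("scores_path is required unless the run simulates its own panel")


def _substream_seed(seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the requested analyses; returns the manifest dict.

    Row-level problems (empty subsets, undefined metrics) are logged and
    recorded in the reports without aborting the run.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[dict] = []

    def register(path: Path, params: dict) -> None:
        outputs.append(
            {"file": path.name, "sha256": _sha256(path), "params": params}
        )

    matrix: ScoreMatrix | None = None
    if "simulate" in cfg.analyses:
        sim = cfg.sim_config or her2_default_config()
        sim = replace(sim, seed=_substream_seed(cfg.seed, "simulate"))
        matrix, _truth = simulate_panel(sim)
        logger.info("simulated panel: %d cases x %d raters", matrix.n_cases, matrix.n_observers)
        scores_out = cfg.out_dir / "simulated_scores.csv"
        rio.write_score_matrix(matrix, scores_out)
        register(scores_out, {"seed": sim.seed, "config": sim.to_json_dict()})
        if matrix.observer_meta:
            p = cfg.out_dir / "simulated_observer_meta.csv"
            rio.write_observer_meta(matrix.observer_meta, p)
            register(p, {"seed": sim.seed})
        if matrix.case_meta:
            p = cfg.out_dir / "simulated_case_meta.csv"
            rio.write_case_meta(matrix.case_meta, p)
            register(p, {"seed": sim.seed})
    if cfg.scores_path is not None:
        matrix = rio.read_score_matrix(cfg.scores_path, HER2_SCHEMA, transposed=cfg.transposed)
        if cfg.observer_meta_path is not None:
            matrix.observer_meta = rio.read_observer_meta(cfg.observer_meta_path)
        if cfg.case_meta_path is not None:
            matrix.case_meta = rio.read_case_meta(cfg.case_meta_path)
    assert matrix is not None

    if "table1" in cfg.analyses:
        reports = table1_report(matrix)
        for rep in reports:
            for note in rep.notes:
                logger.warning("%s: %s", rep.grouping_name, note)
        tsv = cfg.out_dir / "agreement_table.tsv"
        tsv.write_text(render_table1(reports, digits=cfg.display_digits))
        register(tsv, {"digits": cfg.display_digits})
        js = cfg.out_dir / "agreement_table.json"
        _write_json([rep.to_dict() for rep in reports], js)
        register(js, {})
        profile = cfg.out_dir / "case_vote_profile.tsv"
        rio.export_case_vote_profile(matrix, profile)
        register(profile, {})
        marginals = cfg.out_dir / "rater_marginals.tsv"
        rio.export_rater_marginals(matrix, marginals)
        register(marginals, {})

    if "crosstabs" in cfg.analyses:
        anchors = [SubsetSpec(c) for c in matrix.schema.codes]
        ratings = subset_rating_counts(matrix, anchors)
        p = cfg.out_dir / "subset_rating_counts.tsv"
        ratings.to_csv(p, sep="\t")
        register(p, {"anchors": [s.anchor_code for s in anchors]})
        cooc = subset_case_cooccurrence(matrix, anchors)
        p = cfg.out_dir / "subset_case_cooccurrence.tsv"
        cooc.to_csv(p, sep="\t")
        register(p, {"anchors": [s.anchor_code for s in anchors]})

    if "onest" in cfg.analyses:
        target = matrix
        params: dict = {}
        if cfg.onest_subset is not None:
            spec = SubsetSpec(matrix.schema.code_of(cfg.onest_subset))
            target = select_subset(target, spec)
            params["subset"] = cfg.onest_subset
        if cfg.onest_recode is not None:
            target = recode(target, builtin_recode(cfg.onest_recode))
            params["recode"] = cfg.onest_recode
        ocfg = cfg.onest or ONESTConfig()
        ocfg = replace(ocfg, seed=_substream_seed(cfg.seed, "onest"))
        curves = onest_curves(target, ocfg)
        curves_path = cfg.out_dir / "onest_curves.tsv"
        band_path = cfg.out_dir / "onest_band.tsv"
        curves.export(curves_path, band_path)
        params.update(
            {"n_permutations": ocfg.n_permutations, "seed": ocfg.seed, "epsilon": ocfg.plateau_epsilon}
        )
        register(curves_path, params)
        register(band_path, params)
        _write_json({"plateau_k": curves.plateau_k, **params}, cfg.out_dir / "onest_plateau.json")
        register(cfg.out_dir / "onest_plateau.json", params)

    if "stratified" in cfg.analyses:
        results = {}
        if matrix.observer_meta:
            results["observer_experience"] = stratified_opa(matrix, "observer_experience").to_dict()
        if matrix.case_meta:
            results["specimen_type"] = stratified_opa(matrix, "specimen_type").to_dict()
        if not results:
            raise ValueError(
                "stratified analysis requested but no metadata sidecar was provided "
                "(need an observer experience or case specimen-type CSV)"
            )
        p = cfg.out_dir / "stratified_opa.json"
        _write_json(results, p)
        register(p, {})

    manifest = {
        "analyses": list(cfg.analyses),
        "seed": cfg.seed,
        "inputs": {
            "scores": None if cfg.scores_path is None else str(cfg.scores_path),
            "observer_meta": None if cfg.observer_meta_path is None else str(cfg.observer_meta_path),
            "case_meta": None if cfg.case_meta_path is None else str(cfg.case_meta_path),
        },
        "outputs": outputs,
    }
    _write_json(manifest, cfg.out_dir / "manifest.json")
    return manifest
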