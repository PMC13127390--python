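"""ONEST: Observers Needed to Evaluate a Subjective Test.

The procedure traces how overall percent agreement (OPA) decays as the
observer panel grows.  For a random ordering p of the R observers and each
panel size k in 2..R, ``O_p(k)`` is the OPA restricted to the first k
observers of p.  Repeating over many orderings yields a curve family whose
per-k minimum / mean / maximum band summarizes how quickly agreement
stabilizes; the plateau estimate is the smallest panel size from which the
mean curve stays within a tolerance of its final value, i.e. how many
observers are needed before adding more no longer changes the agreement
estimate.

Each curve is non-increasing in k (unanimity among k+1 observers implies
unanimity among the first k), and the mean curve at k = R equals the
full-panel OPA exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ScoreMatrix

__all__ = ["ONESTConfig", "ONESTCurveSet", "onest_curves", "plateau"]


@dataclass(frozen=True)
class ONESTConfig:
    """Resampling parameters for the ONEST procedure.

    n_permutations:
        Observer orderings to sample (uniform, with replacement).
    seed:
        Seed for the ordering sampler; required for reproducibility.
    exhaustive:
        Enumerate all R! orderings instead of sampling; only allowed while
        R! <= ``exhaustive_cap``.
    plateau_epsilon:
        Tolerance (in OPA units) defining the plateau on the mean curve.
    """

    n_permutations: int = 1000
    seed: int = 0
    exhaustive: bool = False
    plateau_epsilon: float = 0.01
    exhaustive_cap: int = 50_000

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.plateau_epsilon <= 0:
            raise ValueError("plateau_epsilon must be > 0")


@dataclass
class ONESTCurveSet:
    """A family of OPA-vs-panel-size curves and its summary band.

    ``curves[p, j]`` is O_p(sizes[j]) for ordering p; ``band`` holds per-k
    min / mean / max over orderings; ``plateau_k`` is the plateau estimate
    at the config's epsilon.
    """

    sizes: np.ndarray  # panel sizes 2..R
    curves: np.ndarray  # n_permutations x len(sizes)
    band: pd.DataFrame  # index = sizes, columns = min / mean / max
    plateau_k: int
    config: ONESTConfig

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (permutation, n_observers, opa) table for replotting."""
        n_perm, n_sizes = self.curves.shape
        return pd.DataFrame(
            {
                "permutation": np.repeat(np.arange(n_perm), n_sizes),
                "n_observers": np.tile(self.sizes, n_perm),
                "opa": self.curves.ravel(),
            }
        )

    def export(self, curves_path: str | Path, band_path: str | Path) -> None:
        self.to_long_frame().to_csv(curves_path, sep="\t", index=False)
        band = self.band.copy()
        band.index.name = "n_observers"
        band.to_csv(band_path, sep="\t")


def _prefix_agreement_lengths(scores: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Per case: length of the longest unanimous observer prefix under ``order``."""
    ordered = scores[:, order]
    differs = ordered != ordered[:, [0]]
    any_diff = differs.any(axis=1)
    first = np.where(any_diff, differs.argmax(axis=1), scores.shape[1])
    return first


def onest_curves(m: ScoreMatrix, cfg: ONESTConfig) -> ONESTCurveSet:
    """Compute the ONEST curve family for a score matrix.

    Sampled mode draws ``cfg.n_permutations`` independent uniform observer
    orderings (seeded); exhaustive mode enumerates all R! orderings when
    R! does not exceed the cap.
    """
    r = m.n_observers
    if r < 3:
        raise ValueError("ONEST needs at least 3 observers (a 2-observer panel is a single point)")
    if cfg.exhaustive:
        if math.factorial(r) > cfg.exhaustive_cap:
            raise ValueError(
                f"exhaustive mode refused: {r}! = {math.factorial(r)} orderings "
                f"exceeds the cap of {cfg.exhaustive_cap}"
            )
        orders = [np.array(p) for p in permutations(range(r))]
    else:
        rng = np.random.default_rng(cfg.seed)
        orders = [rng.permutation(r) for _ in range(cfg.n_permutations)]

    sizes = np.arange(2, r + 1)
    curves = np.empty((len(orders), len(sizes)))
    for p, order in enumerate(orders):
        lengths = _prefix_agreement_lengths(m.scores, order)
        # unanimous among the first k observers iff the agreeing prefix covers them
        curves[p] = (lengths[:, None] >= sizes[None, :]).mean(axis=0)

    band = pd.DataFrame(
        {"min": curves.min(axis=0), "mean": curves.mean(axis=0), "max": curves.max(axis=0)},
        index=pd.Index(sizes, name="n_observers"),
    )
    cs = ONESTCurveSet(sizes=sizes, curves=curves, band=band, plateau_k=r, config=cfg)
    cs.plateau_k = plateau(cs, cfg.plateau_epsilon)
    return cs


def plateau(cs: ONESTCurveSet, epsilon: float | None = None) -> int:
    """Smallest panel size from which the mean curve stays within epsilon
    of its value at the full panel; the full panel size if none earlier."""
    eps = cs.config.plateau_epsilon if epsilon is None else epsilon
    mean = cs.band["mean"].to_numpy()
    within = np.abs(mean - mean[-1]) <= eps
    # suffix condition: all k' >= k within epsilon
    ok_from = np.flip(np.logical_and.accumulate(np.flip(within)))
    idx = int(np.argmax(ok_from)) if ok_from.any() else len(mean) - 1
    return int(cs.sizes[idx])
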