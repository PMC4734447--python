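"""In-silico DNA-DNA hybridization (DDH) prediction from alignment distance.

The genome-to-genome distance ``d`` pools identical and total alignment
columns over every fragment retained by the ANI computation in *both*
directions: ``d = 1 - sum(identical) / sum(columns)``.  Pooling makes the
distance symmetric by construction.

The distance is mapped to a predicted hybridization percentage through a
logistic model ``DDH = 100 / (1 + exp(alpha + beta * d))`` with
``beta > 0`` (monotone decreasing in d).  The bundled default model
(alpha = -5, beta = 83) is a calibration on the package's own simulator
chosen so that d = 0 predicts >= 99% and d = 0.05 sits at the classical
70% species boundary, keeping the DDH verdict consistent with the 95% ANI
boundary; it is a configurable model file, not a literature regression.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from . import anicalc, seqio

__all__ = ["GenomeDistance", "DdhModel", "DdhEstimate", "genome_distance",
           "distance_from_oneway", "ddh_estimate", "ddh", "DEFAULT_MODEL"]


@dataclass(frozen=True)
class GenomeDistance:
    genome_a: str
    genome_b: str
    d: float | None          # None = no retained fragment in either direction
    n_identical: int = 0
    n_columns: int = 0

    @property
    def no_signal(self) -> bool:
        return self.d is None


@dataclass(frozen=True)
class DdhModel:
    """Logistic mapping from distance to predicted DDH percent."""

    alpha: float = -5.0
    beta: float = 83.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive (DDH decreasing in d)")
        if 100.0 / (1.0 + math.exp(self.alpha)) < 99.0:
            raise ValueError("model must predict >= 99% DDH at d = 0")

    def predict(self, d: float) -> float:
        return 100.0 / (1.0 + math.exp(self.alpha + self.beta * d))

    @classmethod
    def load(cls, path: str | Path) -> "DdhModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(alpha=float(obj["alpha"]), beta=float(obj["beta"]))


DEFAULT_MODEL = DdhModel()


@dataclass(frozen=True)
class DdhEstimate:
    genome_a: str
    genome_b: str
    predicted_ddh: float
    d: float
    model: DdhModel


def distance_from_oneway(genome_a: str, genome_b: str, fwd: anicalc.OnewayAni,
                         rev: anicalc.OnewayAni) -> GenomeDistance:
    """Pool the per-fragment columns of two precomputed ANI directions
    (lets callers share alignments between ANI and DDH)."""
    n_id = fwd.n_identical + rev.n_identical
    n_cols = fwd.n_columns + rev.n_columns
    if n_cols == 0:
        return GenomeDistance(genome_a, genome_b, None)
    return GenomeDistance(genome_a, genome_b, 1.0 - n_id / n_cols, n_id, n_cols)


def genome_distance(a: seqio.GenomeRecord, b: seqio.GenomeRecord,
                    params: anicalc.AniParams = anicalc.AniParams()) -> GenomeDistance:
    """Pooled-column alignment distance over both ANI directions."""
    fwd = anicalc.ani_oneway(a, b, params)
    rev = anicalc.ani_oneway(b, a, params)
    return distance_from_oneway(a.genome_id, b.genome_id, fwd, rev)


def ddh_estimate(gd: GenomeDistance, model: DdhModel = DEFAULT_MODEL) -> DdhEstimate | None:
    """Predicted DDH percent for one genome distance (None on no-signal)."""
    if gd.no_signal:
        return None
    return DdhEstimate(gd.genome_a, gd.genome_b, model.predict(gd.d), gd.d, model)


def ddh(a: seqio.GenomeRecord, b: seqio.GenomeRecord,
        params: anicalc.AniParams = anicalc.AniParams(),
        model: DdhModel = DEFAULT_MODEL) -> DdhEstimate | None:
    """Convenience: genome distance followed by the logistic prediction."""
    return ddh_estimate(genome_distance(a, b, params), model)
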