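"""Virtual species: environmental responses and realised distributions.

Each virtual species responds to seven environmental layers chosen at
random from the stack.  The chosen layers are centred, scaled, and
summarised by principal components analysis; the probability that species
``i`` occurs in cell ``j`` is a logistic function of the first two
component scores and their squares:

    logit(p_ij) = alpha_i + sum_{k=1,2} (beta_1ki * V_kj + beta_2ki * V_kj^2)

A single realised presence/absence map is drawn cell-wise from
Bernoulli(p_ij).  Species whose realised map occupies too little of the
extent (prevalence < 0.01 or fewer than 8 cells) are rejected and
redrawn, mimicking the exclusion of species too rare to model.

Coefficient distributions (the generator's own choice; results are
qualitative, not tied to any particular draw): alpha ~ U(-4, 0) keeps
most species at low-to-moderate prevalence, beta_1k ~ U(-4, 4) gives
varied, fairly steep directional responses, and beta_2k ~ U(-4, 0)
restricts quadratic terms to concave (unimodal niche) shapes.  Steep
responses saturate the logistic over much of the extent, so realised
maps are coherent range blocks rather than noise-dominated scatter —
the regime in which distribution modelling is a sensible exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (logit used by callers/tests)

from .envfields import EnvStack
from .errors import (
    GenerationStuckError,
    InsufficientEnvironmentError,
    InvalidParameterError,
    InvalidRequestError,
)

N_CHOSEN_VARS = 7


@dataclass(frozen=True)
class SpeciesResponseCoefficients:
    """A species' environmental response: PCA projection plus coefficients."""

    alpha: float
    beta1: np.ndarray          # (2,) linear coefficients on PC1, PC2
    beta2: np.ndarray          # (2,) quadratic coefficients (<= 0)
    chosen_vars: tuple[str, ...]
    pc_loadings: np.ndarray    # (7, 2) variable loadings
    var_means: np.ndarray      # (7,) training means of chosen variables
    var_sds: np.ndarray        # (7,) training standard deviations
    score_sds: np.ndarray      # (2,) standardisation of the component scores


@dataclass(frozen=True)
class OccurrenceProbabilitySurface:
    """Per-cell occurrence probability and the component scores behind it."""

    p: np.ndarray          # (n_cells,) in [0, 1]
    pc_scores: np.ndarray  # (n_cells, 2)


@dataclass(frozen=True)
class RealizedDistribution:
    """One realised presence/absence map."""

    presence: np.ndarray   # (n_cells,) of {0, 1}

    @property
    def prevalence(self) -> float:
        return float(self.presence.mean())

    @property
    def n_occupied(self) -> int:
        return int(self.presence.sum())


@dataclass
class Community:
    """An ordered collection of virtual species on one grid.

    ``presence`` is the (n_cells, n_species) realised 0/1 matrix; the
    coefficient and probability records are optional (a community loaded
    from a realised-presence table carries only the maps).
    """

    presence: np.ndarray
    coefficients: list[SpeciesResponseCoefficients] = field(default_factory=list)
    surfaces: list[OccurrenceProbabilitySurface] = field(default_factory=list)
    rejections: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.presence.shape[1]

    @property
    def prevalence(self) -> np.ndarray:
        return self.presence.mean(axis=0)

    def realized(self, i: int) -> RealizedDistribution:
        return RealizedDistribution(self.presence[:, i])

    def coefficients_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.coefficients):
            rows.append({
                "species": i, "alpha": c.alpha,
                "beta1_pc1": c.beta1[0], "beta1_pc2": c.beta1[1],
                "beta2_pc1": c.beta2[0], "beta2_pc2": c.beta2[1],
                "chosen_vars": "|".join(c.chosen_vars),
            })
        return pd.DataFrame(rows)

    def presence_frame(self, grid) -> pd.DataFrame:
        cols = {f"sp{i}": self.presence[:, i] for i in range(self.size)}
        return pd.DataFrame({"cell_id": grid.cell_ids, **cols})

    @classmethod
    def from_presence_frame(cls, frame: pd.DataFrame) -> "Community":
        sp_cols = [c for c in frame.columns if c.startswith("sp")]
        if not sp_cols:
            raise InvalidParameterError("presence table has no species columns")
        sp_cols = sorted(sp_cols, key=lambda c: int(c[2:]))
        mat = frame.sort_values("cell_id")[sp_cols].to_numpy(dtype=np.uint8)
        return cls(presence=mat)


def draw_species_response(env: EnvStack, seed: int) -> SpeciesResponseCoefficients:
    """Draw one species' chosen variables, PCA projection, and coefficients."""
    if len(env) < N_CHOSEN_VARS:
        raise InsufficientEnvironmentError(
            f"need >= {N_CHOSEN_VARS} layers, stack has {len(env)}")
    rng = np.random.default_rng(seed)
    chosen = tuple(rng.choice(env.names, size=N_CHOSEN_VARS, replace=False))
    x = env.matrix(list(chosen))
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    xs = (x - means) / sds
    # correlation-matrix PCA via SVD of the standardised data
    _, s, vt = np.linalg.svd(xs, full_matrices=False)
    loadings = vt[:2].T.copy()  # (7, 2)
    # deterministic sign: largest-magnitude loading entry positive
    for k in range(2):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    scores = xs @ loadings
    score_sds = scores.std(axis=0)
    alpha = float(rng.uniform(-4.0, 0.0))
    beta1 = rng.uniform(-4.0, 4.0, size=2)
    beta2 = rng.uniform(-4.0, 0.0, size=2)
    return SpeciesResponseCoefficients(
        alpha=alpha, beta1=beta1, beta2=beta2, chosen_vars=chosen,
        pc_loadings=loadings, var_means=means, var_sds=sds,
        score_sds=score_sds)


def occurrence_probability(coeffs: SpeciesResponseCoefficients,
                           env: EnvStack) -> OccurrenceProbabilitySurface:
    """Evaluate the quadratic-logistic occurrence probability surface."""
    x = env.matrix(list(coeffs.chosen_vars))
    xs = (x - coeffs.var_means) / coeffs.var_sds
    v = (xs @ coeffs.pc_loadings) / coeffs.score_sds
    eta = (coeffs.alpha
           + v @ coeffs.beta1
           + (v ** 2) @ coeffs.beta2)
    return OccurrenceProbabilitySurface(p=expit(eta), pc_scores=v)


def realize(surface: OccurrenceProbabilitySurface, seed: int
            ) -> RealizedDistribution:
    """Draw one presence/absence map: independent Bernoulli(p_j) per cell."""
    rng = np.random.default_rng(seed)
    presence = (rng.random(surface.p.shape[0]) < surface.p).astype(np.uint8)
    return RealizedDistribution(presence=presence)


def generate_community(env: EnvStack, n_species: int, seed: int,
                       prevalence_floor: float = 0.01,
                       min_occupied: int = 8,
                       max_rejections: int = 1000) -> Community:
    """Generate a community, rejecting species below the rarity floor.

    Each species is drawn (response -> probability surface -> realised
    map) with fresh sub-seeds until the realised map has prevalence
    >= ``prevalence_floor`` and at least ``min_occupied`` occupied cells.
    """
    if n_species < 1:
        raise InvalidParameterError("n_species must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_species)
    presence = np.empty((env.grid.n_cells, n_species), dtype=np.uint8)
    coeffs_list, surfaces, rejections = [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        n_rej = 0
        while True:
            s1 = int(rng.integers(0, 2**31 - 1))
            s2 = int(rng.integers(0, 2**31 - 1))
            coeffs = draw_species_response(env, s1)
            surface = occurrence_probability(coeffs, env)
            dist = realize(surface, s2)
            if (dist.prevalence >= prevalence_floor
                    and dist.n_occupied >= min_occupied):
                break
            n_rej += 1
            if n_rej > max_rejections:
                raise GenerationStuckError(
                    f"species {i}: > {max_rejections} rejections")
        presence[:, i] = dist.presence
        coeffs_list.append(coeffs)
        surfaces.append(surface)
        rejections.append(n_rej)
    return Community(presence=presence, coefficients=coeffs_list,
                     surfaces=surfaces, rejections=rejections)


def select_modeled_species(community: Community, n: int, seed: int
                           ) -> np.ndarray:
    """Uniform sample (without replacement) of species indices to model.

    The same subset is reused across every bias / sample-size / method
    arm of an experiment so all arms model the same true distributions.
    """
    if n > community.size:
        raise InvalidRequestError(
            f"requested {n} of {community.size} species")
    rng = np.random.default_rng(seed)
    idx = rng.choice(community.size, size=n, replace=False)
    return np.sort(idx)
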