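"""Spatially biased checklist sampling of a virtual community.

A :class:`BiasTemplate` gives each cell a relative sampling weight
(maximum exactly 1).  Templates are either calibrated synthetically —
weights ``w_a proportional to exp(gamma * z_a)`` for a fixed smooth field
``z``, with ``gamma`` bisected until the weights' Simpson evenness hits a
target — or derived from a real record table by dividing per-cell record
counts by the maximum count.

Checklist simulation then repeatedly (1) draws a cell with probability
proportional to the template weight, (2) redraws if no species is present
there, (3) draws a fixed number of species with replacement from the
species present in the cell, weighting by each species' global realised
prevalence (common species are recorded more readily), and (4) collapses
duplicate draws into the event's detected set.  Sampling stops once the
number of unique (event, species) records reaches
``mean_records_per_species x community size``.

Non-detections are inferred target-group style: a species absent from a
checklist on which other species were recorded contributes a 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .envfields import gaussian_field
from .errors import (
    CalibrationError,
    EmptyEffortError,
    InvalidParameterError,
    ParseError,
    UnsampleableCommunityError,
)
from .grid import GridExtent, simpson_evenness
from .species import Community

#: default Simpson-evenness targets of the four bias levels
DEFAULT_BIAS_LEVELS: dict[str, float] = {
    "none": 1.0,
    "low": 0.762,
    "median": 0.126,
    "severe": 0.021,
}

#: default sample-size grid (mean records per species)
DEFAULT_SAMPLE_SIZES: tuple[int, ...] = (2, 5, 10, 50, 100, 200)

# smooth-field range (km) behind synthetic bias templates
_TEMPLATE_FIELD_RANGE_KM = 50.0


@dataclass(frozen=True)
class BiasTemplate:
    """Per-cell relative sampling weights with measured Simpson evenness."""

    relative_weight: np.ndarray
    evenness: float
    label: str = "custom"

    def __post_init__(self):
        w = np.asarray(self.relative_weight, dtype=float)
        if w.size == 0 or np.any(w < 0):
            raise InvalidParameterError("weights must be non-negative")
        if abs(w.max() - 1.0) > 1e-9:
            raise InvalidParameterError("maximum relative weight must be 1")


def calibrate_bias_template(grid: GridExtent, target_evenness: float,
                            seed: int = 0, tol: float = 0.01,
                            label: str = "custom",
                            anchor: np.ndarray | None = None,
                            anchor_weight: float = 0.5,
                            max_gamma: float = 1e4) -> BiasTemplate:
    """Calibrate exp-field weights to a target Simpson evenness.

    Weights are ``exp(gamma * z)`` for a smooth field ``z``; their
    evenness decreases monotonically in ``gamma`` for fixed ``z``, so a
    simple bisection suffices.  A target of 1 short-circuits to uniform
    weights.

    ``anchor`` optionally mixes an environmental covariate (standardised)
    into ``z`` with weight ``anchor_weight``: real recording effort is
    exogenously biased *through* environmental space (accessibility,
    human presence), not independently of it, and that coupling is what
    lets spatial bias distort covariate-based models.
    """
    n = grid.n_cells
    if not (1.0 / n < target_evenness <= 1.0):
        raise InvalidParameterError(
            f"target evenness must be in (1/{n}, 1]")
    if tol < 0.005:
        raise InvalidParameterError("tol must be >= 0.005")
    if target_evenness >= 1.0 - 1e-12:
        return BiasTemplate(np.ones(n), evenness=1.0, label=label)
    z = gaussian_field(grid, _TEMPLATE_FIELD_RANGE_KM, seed)
    if anchor is not None:
        a = np.asarray(anchor, dtype=float)
        if a.shape != (n,):
            raise InvalidParameterError("anchor must have one value per cell")
        a = (a - a.mean()) / a.std()
        z = np.sqrt(anchor_weight) * a + np.sqrt(1.0 - anchor_weight) * z
        z = (z - z.mean()) / z.std()

    def weights(gamma: float) -> np.ndarray:
        return np.exp(gamma * (z - z.max()))  # max weight exactly 1

    def evenness(gamma: float) -> float:
        return simpson_evenness(weights(gamma)).evenness

    lo, hi = 0.0, 1.0
    while evenness(hi) > target_evenness:
        hi *= 2.0
        if hi > max_gamma:
            raise CalibrationError(
                f"evenness target {target_evenness} unreachable")
    gamma, best_err = hi, abs(evenness(hi) - target_evenness)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        e_mid = evenness(mid)
        if abs(e_mid - target_evenness) < best_err:
            gamma, best_err = mid, abs(e_mid - target_evenness)
        if best_err <= tol * 0.1:
            break
        if e_mid > target_evenness:
            lo = mid
        else:
            hi = mid
    w = weights(gamma)
    e = simpson_evenness(w).evenness
    if abs(e - target_evenness) > tol:
        raise CalibrationError(
            f"calibration stalled at evenness {e:.4f} for target "
            f"{target_evenness}")
    return BiasTemplate(relative_weight=w, evenness=float(e), label=label)


def template_from_records(records: pd.DataFrame, grid: GridExtent,
                          label: str = "custom") -> BiasTemplate:
    """Bias template from a record table: per-cell count / maximum count."""
    if len(records) == 0:
        raise EmptyEffortError("record table is empty")
    if "cell_id" not in records.columns:
        raise ParseError("record table needs a cell_id column")
    counts = np.zeros(grid.n_cells)
    pos = grid._position_of_id
    vals, cnt = np.unique(records["cell_id"].to_numpy(), return_counts=True)
    for cid, k in zip(vals, cnt):
        p = pos.get(int(cid))
        if p is None:
            raise ParseError(f"record cell_id {cid} not an active grid cell")
        counts[p] = k
    w = counts / counts.max()
    return BiasTemplate(relative_weight=w,
                        evenness=simpson_evenness(counts).evenness,
                        label=label)


@dataclass
class ChecklistSet:
    """Simulated sampling events (checklists) with their detected species."""

    event_cells: np.ndarray           # (n_events,) positional cell index
    detected: list[np.ndarray]        # per-event sorted species indices
    target_mean_records_per_species: float
    n_species: int
    n_empty_redraws: int = 0

    @property
    def n_events(self) -> int:
        return self.event_cells.size

    @property
    def total_records(self) -> int:
        return int(sum(len(d) for d in self.detected))

    def record_counts_by_cell(self, grid: GridExtent) -> np.ndarray:
        counts = np.zeros(grid.n_cells)
        for c, d in zip(self.event_cells, self.detected):
            counts[c] += len(d)
        return counts

    def species_record_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_species, dtype=int)
        for d in self.detected:
            counts[d] += 1
        return counts


def simulate_checklists(community: Community, template: BiasTemplate,
                        mean_records_per_species: float,
                        draws_per_event: int = 10,
                        seed: int = 0,
                        max_events: int = 2_000_000) -> ChecklistSet:
    """Simulate checklist sampling until the record target is reached.

    Records are unique (event, species) pairs; duplicate within-event
    draws collapse.  Cells with no present species are redrawn (and
    counted), since a presence-only recording process cannot produce an
    empty checklist.
    """
    if mean_records_per_species <= 0:
        raise InvalidParameterError("mean_records_per_species must be > 0")
    if draws_per_event < 1:
        raise InvalidParameterError("draws_per_event must be >= 1")
    presence = community.presence
    n_cells, n_species = presence.shape
    w = np.asarray(template.relative_weight, dtype=float)
    if w.shape != (n_cells,):
        raise InvalidParameterError("template does not match the grid")
    occupied = presence.any(axis=1)
    if not np.any(w[occupied] > 0):
        raise UnsampleableCommunityError(
            "bias template has zero weight on every occupied cell")
    prevalence = community.prevalence
    # per-cell cumulative species-selection distributions
    cell_species: list[np.ndarray | None] = [None] * n_cells
    cell_cum: list[np.ndarray | None] = [None] * n_cells
    cell_probs = w / w.sum()
    rng = np.random.default_rng(seed)
    target_records = mean_records_per_species * n_species
    event_cells: list[int] = []
    detected: list[np.ndarray] = []
    n_records = 0
    n_empty = 0
    while n_records < target_records:
        batch = rng.choice(n_cells, size=256, p=cell_probs)
        for c in batch:
            if n_records >= target_records:
                break
            if not occupied[c]:
                n_empty += 1
                continue
            if cell_species[c] is None:
                present = np.flatnonzero(presence[c])
                pw = prevalence[present]
                cell_species[c] = present
                cell_cum[c] = np.cumsum(pw) / pw.sum()
            draws = np.searchsorted(cell_cum[c], rng.random(draws_per_event))
            det = np.unique(cell_species[c][draws])
            event_cells.append(int(c))
            detected.append(det)
            n_records += det.size
        if len(event_cells) > max_events:
            raise UnsampleableCommunityError(
                "event budget exhausted before reaching the record target")
    return ChecklistSet(event_cells=np.asarray(event_cells, dtype=int),
                        detected=detected,
                        target_mean_records_per_species=float(mean_records_per_species),
                        n_species=n_species,
                        n_empty_redraws=n_empty)


@dataclass(frozen=True)
class DetectionMatrix:
    """Events x modeled-species detection/non-detection matrix."""

    matrix: np.ndarray        # (n_events, n_modeled) of {0, 1}
    species: np.ndarray       # modeled species indices (columns)
    event_cells: np.ndarray   # (n_events,) positional cell index

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]


def infer_nondetections(checklists: ChecklistSet,
                        modeled_species) -> DetectionMatrix:
    """Target-group non-detection inference for the modeled species subset."""
    if checklists.n_events == 0:
        raise EmptyEffortError("checklist set is empty")
    species = np.asarray(modeled_species, dtype=int)
    col_of = {int(s): j for j, s in enumerate(species)}
    mat = np.zeros((checklists.n_events, species.size), dtype=np.uint8)
    for i, det in enumerate(checklists.detected):
        for s in det:
            j = col_of.get(int(s))
            if j is not None:
                mat[i, j] = 1
    return DetectionMatrix(matrix=mat, species=species,
                           event_cells=checklists.event_cells.copy())


# -- record-table I/O -----------------------------------------------------

_RECORD_COLUMNS = ["event_id", "cell_id", "species", "surrogate_date",
                   "observer"]


def records_frame(checklists: ChecklistSet, grid: GridExtent) -> pd.DataFrame:
    """Flatten a checklist set into a record table (one row per record).

    ``surrogate_date`` and ``observer`` are synthetic stand-ins derived
    from the event index, present so the table matches the shape of real
    biological-records exports.
    """
    rows = []
    base = pd.Timestamp("2000-01-01")
    for e, (c, det) in enumerate(zip(checklists.event_cells,
                                     checklists.detected)):
        date = (base + pd.Timedelta(days=int(e))).date().isoformat()
        for s in det:
            rows.append((e, int(grid.cell_ids[c]), int(s), date,
                         f"obs{e % 97}"))
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def write_records(checklists: ChecklistSet, grid: GridExtent, path) -> None:
    records_frame(checklists, grid).to_csv(path, index=False)


def read_records(path, grid: GridExtent, n_species: int | None = None,
                 mean_records_per_species: float = float("nan")
                 ) -> ChecklistSet:
    """Rebuild a :class:`ChecklistSet` from a record CSV."""
    frame = pd.read_csv(path)
    missing = [c for c in _RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"record table missing columns {missing}")
    for col in ("event_id", "cell_id", "species"):
        try:
            frame[col] = frame[col].astype(int)
        except (ValueError, TypeError) as exc:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2 if len(bad) else None
            raise ParseError(f"non-integer value in column {col!r}",
                             line=line) from exc
    pos = grid._position_of_id
    event_cells, detected = [], []
    for _, sub in frame.groupby("event_id", sort=True):
        cid = int(sub["cell_id"].iloc[0])
        if cid not in pos:
            raise ParseError(f"cell_id {cid} not an active grid cell")
        event_cells.append(pos[cid])
        detected.append(np.unique(sub["species"].to_numpy()))
    if n_species is None:
        n_species = int(frame["species"].max()) + 1 if len(frame) else 0
    return ChecklistSet(event_cells=np.asarray(event_cells, dtype=int),
                        detected=detected,
                        target_mean_records_per_species=mean_records_per_species,
                        n_species=n_species)
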