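"""Seeded stimulus generators and cue-current conversion.

Stimuli are abstract feature sets: a stimulus activates a subset of input
neurons by tonic current injection, with no geometry beyond what the
generators impose.

Static protocol (one-layer network): the 512 input neurons are split into
two disjoint category pools of 256; each example activates 128 neurons
drawn from its pool.  Per category, several training examples plus one
reserved novel test example are drawn; the two test examples are combined
into a compound pattern for the segmentation test.

Translating protocol (two-layer network): the input layer is a 32 x 16
grid.  Each category owns a prototype of 16 of the 32 rows; a stimulus
activates 12 of those rows.  A transform extends the active rows across an
8-column window; successive transforms shift the window by 2 columns
(75 % overlap), so translation is orthogonal to the rows that define
stimulus identity.  Category-overlap variants share a few rows between
both prototypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Stimulus",
    "TransformInstance",
    "StimulusSet",
    "GRID_ROWS",
    "GRID_COLS",
    "generate_static_set",
    "generate_translating_set",
    "transforms_of",
    "compound_pattern",
    "to_current",
]

GRID_ROWS = 32
GRID_COLS = 16

#: Column window width of one transform and the per-transform shift.
TRANSFORM_WIDTH = 8
TRANSFORM_SHIFT = 2


@dataclass(frozen=True)
class Stimulus:
    """One stimulus: a feature set belonging to a category.

    For static stimuli ``features`` are neuron indices (128 of 512); for
    translating stimuli they are row indices on the input grid (12 rows).
    """

    category_id: int
    features: tuple[int, ...]
    role: str = "training"  # "training" | "testing"
    kind: str = "static"    # "static" | "translating"

    def __post_init__(self) -> None:
        if self.role not in ("training", "testing"):
            raise ValueError(f"unknown role {self.role!r}")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in stimulus")

    @property
    def label(self) -> str:
        return f"cat{self.category_id}-{self.role}"


@dataclass(frozen=True)
class TransformInstance:
    """One translated instance of a stimulus on the 32 x 16 grid.

    Transform ``t`` (1-based) occupies columns ``2*(t-1) .. 2*(t-1)+7``
    (0-based, inclusive): 12 rows x 8 columns = 96 active neurons,
    row-major indexing.
    """

    stimulus: Stimulus
    transform_index: int
    active_neurons: tuple[int, ...]


@dataclass(frozen=True)
class StimulusSet:
    """A generated collection: category pools plus the drawn stimuli."""

    pools: tuple[tuple[int, ...], ...]
    stimuli: tuple[Stimulus, ...]
    kind: str
    shared_features: tuple[int, ...] = ()
    seed: int | None = None

    def training(self, category_id: int | None = None) -> list[Stimulus]:
        return [s for s in self.stimuli if s.role == "training"
                and (category_id is None or s.category_id == category_id)]

    def testing(self, category_id: int | None = None) -> list[Stimulus]:
        return [s for s in self.stimuli if s.role == "testing"
                and (category_id is None or s.category_id == category_id)]

    @property
    def n_categories(self) -> int:
        return len(self.pools)


def generate_static_set(
    n_train_per_cat: int = 10,
    n_test_per_cat: int = 1,
    seed: int | np.random.Generator = 0,
    n_neurons: int = 512,
    pool_size: int = 256,
    example_size: int = 128,
) -> StimulusSet:
    """Draw the static category stimuli for the one-layer protocol.

    The ``n_neurons`` input cells are split randomly into two disjoint
    pools of ``pool_size``; every example activates ``example_size``
    neurons drawn without replacement from its category's pool.  The last
    ``n_test_per_cat`` examples per category are reserved for testing.
    """
    if pool_size < example_size:
        raise ValueError("pool smaller than example size")
    if 2 * pool_size > n_neurons:
        raise ValueError("pools exceed the input layer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n_neurons)
    pools = (tuple(sorted(perm[:pool_size])),
             tuple(sorted(perm[pool_size:2 * pool_size])))
    stimuli: list[Stimulus] = []
    for cat, pool in enumerate(pools):
        pool_arr = np.asarray(pool)
        for k in range(n_train_per_cat + n_test_per_cat):
            chosen = rng.choice(pool_arr, size=example_size, replace=False)
            role = "training" if k < n_train_per_cat else "testing"
            stimuli.append(Stimulus(category_id=cat,
                                    features=tuple(sorted(int(i) for i in chosen)),
                                    role=role, kind="static"))
    return StimulusSet(pools=pools, stimuli=tuple(stimuli), kind="static")


def generate_translating_set(
    n_train_per_cat: int = 8,
    shared_rows: int = 0,
    seed: int | np.random.Generator = 0,
    n_test_per_cat: int = 1,
    rows_per_stimulus: int = 12,
) -> StimulusSet:
    """Draw the translating stimuli for the two-layer protocol.

    The 32 grid rows are partitioned into ``shared_rows`` rows common to
    both category prototypes plus two disjoint category-specific pools of
    ``(32 - shared_rows) / 2`` rows each.  Every stimulus activates the
    shared rows plus ``rows_per_stimulus - shared_rows`` rows drawn from
    its category pool.  ``shared_rows`` of 2 and 4 reproduce the 16.7 %
    and 33.3 % cross-category overlap variants.
    """
    if shared_rows < 0 or shared_rows % 2 != 0:
        raise ValueError("shared_rows must be a non-negative even integer")
    unique_pool = (GRID_ROWS - shared_rows) // 2
    draw = rows_per_stimulus - shared_rows
    if draw <= 0 or draw > unique_pool:
        raise ValueError(
            f"infeasible shared_rows={shared_rows}: need {draw} rows from "
            f"a pool of {unique_pool}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(GRID_ROWS)
    shared = tuple(sorted(int(r) for r in perm[:shared_rows]))
    rest = perm[shared_rows:]
    cat_pools = (rest[:unique_pool], rest[unique_pool:2 * unique_pool])
    # A category's prototype pool is its unique rows plus any shared rows.
    pools = tuple(
        tuple(sorted(int(r) for r in np.concatenate([perm[:shared_rows], cp])))
        for cp in cat_pools
    )
    stimuli: list[Stimulus] = []
    for cat, cp in enumerate(cat_pools):
        for k in range(n_train_per_cat + n_test_per_cat):
            chosen = rng.choice(cp, size=draw, replace=False)
            rows = tuple(sorted(set(shared) | {int(r) for r in chosen}))
            role = "training" if k < n_train_per_cat else "testing"
            stimuli.append(Stimulus(category_id=cat, features=rows,
                                    role=role, kind="translating"))
    return StimulusSet(pools=pools, stimuli=tuple(stimuli),
                       kind="translating", shared_features=shared)


def _window_columns(t: int) -> np.ndarray:
    """0-based column indices of transform ``t`` (1-based)."""
    start = TRANSFORM_SHIFT * (t - 1)
    if start + TRANSFORM_WIDTH > GRID_COLS:
        raise ValueError(f"transform {t} falls off the {GRID_COLS}-column grid")
    return np.arange(start, start + TRANSFORM_WIDTH)


def transforms_of(stimulus: Stimulus, n_transforms: int = 5) -> list[TransformInstance]:
    """The translation sequence of a stimulus: transforms t = 1..n.

    Consecutive transforms share 6 of their 8 columns (75 % overlap);
    transforms 1 and 5 are column-disjoint.  The active rows never change
    -- identity and translation are orthogonal.
    """
    if stimulus.kind != "translating":
        raise ValueError("transforms are defined for translating stimuli only")
    rows = np.asarray(stimulus.features)
    out = []
    for t in range(1, n_transforms + 1):
        cols = _window_columns(t)
        idx = (rows[:, None] * GRID_COLS + cols[None, :]).ravel()
        out.append(TransformInstance(
            stimulus=stimulus,
            transform_index=t,
            active_neurons=tuple(sorted(int(i) for i in idx)),
        ))
    return out


def compound_pattern(*active_sets: tuple[int, ...] | list[int]) -> tuple[int, ...]:
    """Union of several active-neuron sets (one per simultaneous stimulus).

    Shared neurons appear once: a neuron driven by two stimuli receives
    the single cue current, not a doubled one.
    """
    merged: set[int] = set()
    for s in active_sets:
        merged |= set(int(i) for i in s)
    return tuple(sorted(merged))


def to_current(
    active: tuple[int, ...] | list[int] | np.ndarray,
    n_neurons: int,
    I_cue_nA: float = 0.75,
) -> np.ndarray:
    """Cue-current vector in pA: active neurons get ``I_cue_nA``, rest 0."""
    idx = np.asarray(active, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_neurons):
        raise IndexError("active neuron index outside the layer")
    I = np.zeros(n_neurons)
    I[idx] = I_cue_nA * 1000.0  # nA -> pA
    return I
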