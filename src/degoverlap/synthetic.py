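"""Synthetic gene universes, DEG lists with planted overlap, and expression matrices.

This module generates the inputs the rest of the pipeline consumes, with known
("planted") ground truth, so that differential-expression calling and overlap
statistics can be exercised end to end without any external download.

The generator emulates a two-colour-free microarray-style experiment:

* a gene universe of ~20,000 symbols,
* per-experiment directional DEG lists at realistic scale (order 10^3 genes
  per direction),
* planted intersections between chosen experiments/directions, from tens to
  hundreds of shared genes,
* optional "dual-direction" genes represented by two probe rows of one gene
  symbol with opposite planted directions — the mechanism by which real
  array platforms let one gene appear in both the over- and under-expressed
  list of a single experiment.

Intensity model: baseline log2 intensities are normal (i.e. lognormal on the
linear scale) with mean ``BASELINE_LOG2_MEAN`` and SD ``BASELINE_LOG2_SD``;
replicate noise is normal with per-experiment SD ``sigma``; planted rows are
shifted by ``±effect_log2fc`` in the treatment condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._util import child_rng, normalize_symbol
from .errors import InfeasibleDesignError, InvalidArgumentError

# Baseline intensity distribution (log2 scale). Typical array intensities sit
# around 2^7 with a spread of a couple of log2 units.
BASELINE_LOG2_MEAN = 7.0
BASELINE_LOG2_SD = 1.5

Direction = Literal["over", "under"]
DIRECTIONS: tuple[Direction, Direction] = ("over", "under")


# ---------------------------------------------------------------------------
# Gene universe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneUniverse:
    """The background set of gene identifiers all null models sample from."""

    identifiers: tuple[str, ...]

    def __post_init__(self):
        if len(self.identifiers) < 1:
            raise InvalidArgumentError("universe must contain at least one identifier")
        normed = tuple(normalize_symbol(g) for g in self.identifiers)
        if len(set(normed)) != len(normed):
            raise InvalidArgumentError("universe identifiers must be unique after normalization")
        object.__setattr__(self, "identifiers", normed)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(normed)})

    @property
    def N(self) -> int:
        return len(self.identifiers)

    def __len__(self) -> int:
        return self.N

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self._index

    def __iter__(self):
        return iter(self.identifiers)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.identifiers)

    def indices_of(self, genes: Iterable[str]) -> np.ndarray:
        return np.fromiter((self._index[g] for g in genes), dtype=np.int64)

    @classmethod
    def from_file(cls, path) -> "GeneUniverse":
        from ._util import read_gene_list

        return cls(tuple(read_gene_list(path)))


def make_universe(N: int, seed: int = 0) -> GeneUniverse:
    """Create a universe of ``N`` unique synthetic symbols.

    Symbols are zero-padded indexed names (``SYN00000`` ...) presented in a
    seed-determined order; output is deterministic for a given ``(N, seed)``.
    """
    if N < 1:
        raise InvalidArgumentError(f"universe size must be >= 1, got {N}")
    width = max(5, len(str(N - 1)))
    names = np.array([f"SYN{i:0{width}d}" for i in range(N)])
    order = child_rng(seed, "universe-order").permutation(N)
    return GeneUniverse(tuple(names[order]))


# ---------------------------------------------------------------------------
# Simulation design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentSpec:
    """Planted truth for one two-condition perturbation experiment."""

    name: str
    n_over: int
    n_under: int
    effect_log2fc: float = 1.0   # mean absolute planted shift, log2 units
    sigma: float = 0.25          # within-group noise SD, log2 units
    replicates_per_condition: int = 3


@dataclass(frozen=True)
class SharedBlock:
    """A planted intersection: ``count`` genes shared by the named
    (experiment, direction) slots."""

    experiments: tuple[str, ...]
    directions: tuple[Direction, ...]
    count: int

    def slots(self) -> list[tuple[str, Direction]]:
        return list(zip(self.experiments, self.directions))


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of a synthetic overlap study.

    ``shared_blocks`` pin a minimum exact planted core per intersection;
    unconstrained fill genes may still co-occur by chance (as in real
    experiments) unless ``disjoint_fill`` forces the fills apart.
    Dual-direction genes occupy one slot in *both* directional lists of the
    designated experiment, so list sizes always equal the design counts.
    """

    N: int
    experiments: tuple[ExperimentSpec, ...]
    shared_blocks: tuple[SharedBlock, ...] = ()
    dual_direction_count: int = 0
    dual_direction_experiment: str | None = None
    disjoint_fill: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "experiments", tuple(self.experiments))
        object.__setattr__(self, "shared_blocks", tuple(
            SharedBlock(tuple(b.experiments), tuple(b.directions), b.count)
            if isinstance(b, SharedBlock) else SharedBlock(*b)
            for b in self.shared_blocks
        ))

    def spec_of(self, name: str) -> ExperimentSpec:
        for e in self.experiments:
            if e.name == name:
                return e
        raise InvalidArgumentError(f"no experiment named {name!r} in design")

    def validate(self) -> None:
        if self.N < 1:
            raise InvalidArgumentError("N must be >= 1")
        names = [e.name for e in self.experiments]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("experiment names must be unique")
        for e in self.experiments:
            if e.n_over < 0 or e.n_under < 0:
                raise InvalidArgumentError(f"{e.name}: DEG counts must be >= 0")
            if e.n_over > self.N or e.n_under > self.N:
                raise InvalidArgumentError(f"{e.name}: DEG count exceeds universe size")
            if e.replicates_per_condition < 2:
                raise InvalidArgumentError(
                    f"{e.name}: replicates_per_condition must be >= 2 "
                    "(a p-value is otherwise undefined)"
                )
            if e.sigma < 0:
                raise InvalidArgumentError(f"{e.name}: sigma must be >= 0")
        for i, blk in enumerate(self.shared_blocks):
            if blk.count < 0:
                raise InvalidArgumentError(f"shared_block[{i}]: count must be >= 0")
            if len(blk.experiments) != len(blk.directions) or len(blk.experiments) < 2:
                raise InvalidArgumentError(
                    f"shared_block[{i}]: needs >= 2 (experiment, direction) slots"
                )
            for name, d in blk.slots():
                spec = self.spec_of(name)
                cap = spec.n_over if d == "over" else spec.n_under
                if blk.count > cap:
                    raise InfeasibleDesignError(
                        f"shared_block[{i}] ({blk.experiments}/{blk.directions}, "
                        f"count={blk.count}) exceeds {name}.{d} size {cap}"
                    )
        if self.dual_direction_count < 0:
            raise InvalidArgumentError("dual_direction_count must be >= 0")
        if self.dual_direction_count:
            name = self.dual_direction_experiment or self.experiments[0].name
            spec = self.spec_of(name)
            if self.dual_direction_count > min(spec.n_over, spec.n_under):
                raise InfeasibleDesignError(
                    f"dual_direction_count={self.dual_direction_count} exceeds "
                    f"min directional size of experiment {name!r}"
                )


class GeneLists(NamedTuple):
    """Directional DEG lists of one experiment."""

    over: frozenset[str]
    under: frozenset[str]


@dataclass(frozen=True)
class TruthTable:
    """Exact planted membership: per (experiment, direction), per shared
    block, and the dual-direction genes of each experiment."""

    planted: Mapping[tuple[str, Direction], frozenset[str]]
    block_members: tuple[frozenset[str], ...]
    dual_genes: Mapping[str, frozenset[str]]

    def to_json(self, path) -> None:
        payload = {
            "planted": {f"{e}:{d}": sorted(g) for (e, d), g in self.planted.items()},
            "block_members": [sorted(b) for b in self.block_members],
            "dual_genes": {e: sorted(g) for e, g in self.dual_genes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        planted = {}
        for key, genes in payload["planted"].items():
            e, d = key.rsplit(":", 1)
            planted[(e, d)] = frozenset(genes)
        return cls(
            planted=planted,
            block_members=tuple(frozenset(b) for b in payload["block_members"]),
            dual_genes={e: frozenset(g) for e, g in payload["dual_genes"].items()},
        )


# ---------------------------------------------------------------------------
# List simulation
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, pool: Sequence[str], k: int, what: str) -> list[str]:
    if k > len(pool):
        raise InfeasibleDesignError(
            f"cannot draw {k} genes for {what}: only {len(pool)} unplanted genes remain"
        )
    if k == 0:
        return []
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def simulate_deg_lists(
    design: SimulationDesign, universe: GeneUniverse | None = None
) -> tuple[dict[str, GeneLists], TruthTable]:
    """Generate directional DEG lists with the design's planted structure.

    Planted cores (dual-direction genes and shared blocks) are drawn from a
    global pool of not-yet-planted genes, so distinct blocks never collide.
    Remaining slots of each (experiment, direction) are filled from genes not
    already used by that experiment — or, with ``disjoint_fill``, not used
    anywhere — so chance co-occurrence between experiments is possible (and
    statistically expected) unless disjointness is requested.

    Fill draws use a per-experiment RNG stream, so adding an experiment to a
    design does not perturb the lists of earlier ones.
    """
    design.validate()
    if universe is None:
        universe = make_universe(design.N, design.seed)
    elif universe.N != design.N:
        raise InvalidArgumentError(
            f"universe size {universe.N} does not match design N {design.N}"
        )

    all_ids = list(universe.identifiers)
    planted: dict[tuple[str, Direction], set[str]] = {
        (e.name, d): set() for e in design.experiments for d in DIRECTIONS
    }
    used_any: set[str] = set()

    # Dual-direction genes: one slot in each directional list of one experiment.
    dual_genes: dict[str, frozenset[str]] = {e.name: frozenset() for e in design.experiments}
    if design.dual_direction_count:
        name = design.dual_direction_experiment or design.experiments[0].name
        rng = child_rng(design.seed, "dual", name)
        pool = [g for g in all_ids if g not in used_any]
        genes = _draw(rng, pool, design.dual_direction_count, f"dual-direction genes of {name}")
        dual_genes[name] = frozenset(genes)
        planted[(name, "over")].update(genes)
        planted[(name, "under")].update(genes)
        used_any.update(genes)

    # Shared blocks: each draws a fresh core from the global unplanted pool.
    block_members: list[frozenset[str]] = []
    for i, blk in enumerate(design.shared_blocks):
        for name, d in blk.slots():
            spec = design.spec_of(name)
            cap = spec.n_over if d == "over" else spec.n_under
            if len(planted[(name, d)]) + blk.count > cap:
                raise InfeasibleDesignError(
                    f"shared_block[{i}] ({blk.experiments}/{blk.directions}, "
                    f"count={blk.count}): {name}.{d} has only "
                    f"{cap - len(planted[(name, d)])} free slot(s)"
                )
        rng = child_rng(design.seed, "block", i)
        pool = [g for g in all_ids if g not in used_any]
        genes = _draw(rng, pool, blk.count, f"shared_block[{i}]")
        for name, d in blk.slots():
            planted[(name, d)].update(genes)
        used_any.update(genes)
        block_members.append(frozenset(genes))

    # Fill each list to its target size.
    lists: dict[str, GeneLists] = {}
    for e in design.experiments:
        rng = child_rng(design.seed, "fill", e.name)
        realized: dict[Direction, set[str]] = {d: set(planted[(e.name, d)]) for d in DIRECTIONS}
        for d, target in (("over", e.n_over), ("under", e.n_under)):
            need = target - len(realized[d])
            exclude = realized["over"] | realized["under"]
            if design.disjoint_fill:
                exclude = exclude | used_any
            pool = [g for g in all_ids if g not in exclude]
            fill = _draw(rng, pool, need, f"{e.name}.{d} fill")
            realized[d].update(fill)
            used_any.update(fill)
        lists[e.name] = GeneLists(over=frozenset(realized["over"]),
                                  under=frozenset(realized["under"]))
        planted[(e.name, "over")] = realized["over"]
        planted[(e.name, "under")] = realized["under"]

    truth = TruthTable(
        planted={k: frozenset(v) for k, v in planted.items()},
        block_members=tuple(block_members),
        dual_genes=dual_genes,
    )
    return lists, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionExperiment:
    """A simulated two-condition log2 intensity matrix for one experiment.

    ``frame`` columns: ``probe_id``, ``gene_symbol``, then one column per
    sample named ``<condition>_<replicate>``; ``conditions`` gives the
    condition label of each sample column in order.
    """

    name: str
    frame: pd.DataFrame
    conditions: tuple[str, ...]

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("probe_id", "gene_symbol")]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def simulate_expression(
    design: SimulationDesign, universe: GeneUniverse | None = None
) -> tuple[dict[str, ExpressionExperiment], TruthTable]:
    """Generate per-experiment two-condition log2 intensity matrices.

    Rows are one probe per universe gene plus a second probe for each
    dual-direction gene of the experiment (same gene symbol, opposite planted
    direction). Planted rows are shifted by ``±effect_log2fc`` in the
    treatment condition; all rows carry iid normal noise with SD ``sigma``.
    The planted truth is exactly the one :func:`simulate_deg_lists` produces
    for the same design.
    """
    design.validate()
    if universe is None:
        universe = make_universe(design.N, design.seed)
    lists, truth = simulate_deg_lists(design, universe)

    experiments: dict[str, ExpressionExperiment] = {}
    for e in design.experiments:
        rng = child_rng(design.seed, "expression", e.name)
        r = e.replicates_per_condition
        ids = list(universe.identifiers)
        dual = sorted(truth.dual_genes.get(e.name, frozenset()))
        n_rows = design.N + len(dual)

        probe_ids = [f"P{i:06d}" for i in range(design.N)]
        symbols = list(ids)
        # Second probes for dual-direction genes, same symbol.
        probe_ids += [f"P{design.N + j:06d}" for j in range(len(dual))]
        symbols += dual

        over = lists[e.name].over
        under = lists[e.name].under
        dual_set = set(dual)
        # Primary probe direction: dual genes are 'over' on their first probe.
        delta = np.zeros(n_rows)
        for i, g in enumerate(ids):
            if g in over:
                delta[i] = e.effect_log2fc
            elif g in under:
                delta[i] = -e.effect_log2fc
        for j, g in enumerate(dual):
            delta[design.N + j] = -e.effect_log2fc  # second probe: under
        assert dual_set <= over and dual_set <= under

        baseline = rng.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, size=n_rows)
        noise = rng.normal(0.0, e.sigma, size=(n_rows, 2 * r)) if e.sigma > 0 else np.zeros((n_rows, 2 * r))
        values = baseline[:, None] + noise
        values[:, r:] += delta[:, None]

        columns = [f"control_{i + 1}" for i in range(r)] + [f"treatment_{i + 1}" for i in range(r)]
        frame = pd.DataFrame(values, columns=columns)
        frame.insert(0, "gene_symbol", symbols)
        frame.insert(0, "probe_id", probe_ids)
        experiments[e.name] = ExpressionExperiment(
            name=e.name,
            frame=frame,
            conditions=tuple(["control"] * r + ["treatment"] * r),
        )
    return experiments, truth
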