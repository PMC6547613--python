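"""End-to-end pipeline: simulate → call DEGs → test overlaps → report.

A declarative config (TOML or YAML, or the :class:`PipelineConfig` dataclass
directly) names the experiments (simulated, expression matrix, GEO2R export,
or ready-made gene-list pair), the background universe, the thresholds, and
the comparisons to run (pairwise directional suites and multi-set exact
tests). One master seed drives every random stage through stable sub-seeded
streams, so re-running a config reproduces all numbers exactly and reordering
unrelated sections does not shift any stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from ._util import child_seed, read_gene_list
from .deg import ExperimentDE, apply_thresholds, ingest_geo2r, test_differential
from .errors import ConfigurationError
from .overlap import DirectionalComparison, directional_suite, exact_multiset_test
from .synthetic import (
    ExperimentSpec, GeneUniverse, SharedBlock, SimulationDesign,
    make_universe, simulate_deg_lists, simulate_expression,
)

logger = logging.getLogger(__name__)

EXPERIMENT_KINDS = ("simulated", "matrix", "geo2r", "lists")
COMPARISON_KINDS = ("pairwise", "multiset")


@dataclass
class PipelineConfig:
    """Declarative description of one overlap-analysis run."""

    experiments: list[dict] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=list)
    simulation: SimulationDesign | None = None
    universe_path: str | None = None   # None -> simulated universe
    fc_cut: float = 1.5
    p_cut: float = 0.05
    n_perm: int = 10_000
    alpha: float = 0.05
    master_seed: int = 0
    simulate_mode: str = "lists"       # "lists" | "expression"
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None and not isinstance(sim, SimulationDesign):
            sim = SimulationDesign(
                N=int(sim["N"]),
                experiments=tuple(ExperimentSpec(**e) for e in sim.get("experiments", [])),
                shared_blocks=tuple(
                    SharedBlock(tuple(b["experiments"]), tuple(b["directions"]),
                                int(b["count"]))
                    for b in sim.get("shared_blocks", [])
                ),
                dual_direction_count=int(sim.get("dual_direction_count", 0)),
                dual_direction_experiment=sim.get("dual_direction_experiment"),
                disjoint_fill=bool(sim.get("disjoint_fill", False)),
                seed=int(sim.get("seed", 0)),
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(simulation=sim, **d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            import tomllib

            data = tomllib.loads(text)
        return cls.from_dict(data)

    def canonical_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable issues; empty iff the config can run.

    Never raises: every problem becomes one issue naming the field at fault
    and the remedy.
    """
    issues: list[str] = []
    if config.n_perm < 1:
        issues.append(f"n_perm must be >= 1 (got {config.n_perm}); raise it")
    if config.fc_cut < 1:
        issues.append(f"fc_cut must be >= 1 on the linear scale (got {config.fc_cut})")
    if not (0 < config.p_cut <= 1):
        issues.append(f"p_cut must be in (0, 1] (got {config.p_cut})")
    if config.simulate_mode not in ("lists", "expression"):
        issues.append(f"simulate_mode must be 'lists' or 'expression' (got {config.simulate_mode!r})")

    names = [e.get("name") for e in config.experiments]
    if len(set(names)) != len(names):
        issues.append("experiment names must be unique; rename duplicates")
    declared = set(names)

    needs_sim = False
    for e in config.experiments:
        name = e.get("name", "<unnamed>")
        kind = e.get("kind")
        if kind not in EXPERIMENT_KINDS:
            issues.append(f"experiment {name!r}: kind must be one of {EXPERIMENT_KINDS}")
            continue
        if kind == "simulated":
            needs_sim = True
            if config.simulation is not None:
                sim_names = {s.name for s in config.simulation.experiments}
                if name not in sim_names:
                    issues.append(
                        f"experiment {name!r}: not in simulation design "
                        f"(design has {sorted(sim_names)})"
                    )
        elif kind in ("matrix", "geo2r"):
            path = e.get("path")
            if not path:
                issues.append(f"experiment {name!r}: kind {kind!r} needs a 'path'")
            elif not Path(path).exists():
                issues.append(f"experiment {name!r}: input file {path} not found")
        elif kind == "lists":
            for key in ("over", "under"):
                p = e.get(key)
                if not p:
                    issues.append(f"experiment {name!r}: kind 'lists' needs {key!r} path")
                elif not Path(p).exists():
                    issues.append(f"experiment {name!r}: list file {p} not found")
    if needs_sim and config.simulation is None:
        issues.append("a simulated experiment is declared but no [simulation] section exists")
    if config.universe_path is None and config.simulation is None:
        issues.append("no universe: give universe_path or a [simulation] section")
    if config.universe_path is not None and not Path(config.universe_path).exists():
        issues.append(f"universe file {config.universe_path} not found")
    if config.simulation is not None:
        try:
            config.simulation.validate()
        except Exception as exc:
            issues.append(f"simulation design invalid: {exc}")

    seen = set()
    for c in config.comparisons:
        cname = c.get("name") or _comparison_name(c)
        if cname in seen:
            issues.append(f"comparison {cname!r} appears more than once; name them uniquely")
        seen.add(cname)
        kind = c.get("kind")
        if kind not in COMPARISON_KINDS:
            issues.append(f"comparison {cname!r}: kind must be one of {COMPARISON_KINDS}")
            continue
        if kind == "pairwise":
            refs = [c.get("a"), c.get("b")]
        else:
            refs = list(c.get("experiments", []))
            if len(refs) < 2:
                issues.append(f"comparison {cname!r}: multiset needs >= 2 experiments")
            if c.get("direction") not in ("over", "under"):
                issues.append(f"comparison {cname!r}: multiset needs direction 'over' or 'under'")
        for ref in refs:
            if ref is None:
                issues.append(f"comparison {cname!r}: missing experiment reference")
            elif ref not in declared:
                issues.append(
                    f"comparison {cname!r}: references undeclared experiment {ref!r}; "
                    f"declare it under [[experiments]]"
                )
    return issues


def _comparison_name(c: dict) -> str:
    if c.get("name"):
        return c["name"]
    if c.get("kind") == "pairwise":
        return f"{c.get('a')}_vs_{c.get('b')}"
    return "multiset_" + "_".join(c.get("experiments", [])) + "_" + str(c.get("direction"))


@dataclass
class RunReport:
    """All comparison records of one pipeline run plus provenance."""

    records: list[dict]
    provenance: dict
    warnings: dict

    def to_dict(self, include_timestamp: bool = True) -> dict:
        prov = dict(self.provenance)
        if not include_timestamp:
            prov.pop("timestamp", None)
        return {"records": self.records, "provenance": prov, "warnings": self.warnings}


def _load_experiments(config: PipelineConfig, universe: GeneUniverse,
                      warnings: dict) -> dict[str, ExperimentDE]:
    sim_lists = sim_matrices = None
    if any(e["kind"] == "simulated" for e in config.experiments):
        design = dataclasses.replace(
            config.simulation, seed=child_seed(config.master_seed, "simulate")
        )
        if config.simulate_mode == "expression":
            sim_matrices, truth = simulate_expression(design, universe)
        else:
            sim_lists, truth = simulate_deg_lists(design, universe)
        warnings["planted_dual_direction"] = {
            e: len(g) for e, g in truth.dual_genes.items() if g
        }

    out: dict[str, ExperimentDE] = {}
    for e in config.experiments:
        name, kind = e["name"], e["kind"]
        if kind == "simulated" and sim_lists is not None:
            lists = sim_lists[name]
            out[name] = ExperimentDE(
                name=name, over=lists.over, under=lists.under, universe=universe,
                thresholds=(config.fc_cut, config.p_cut),
            )
            continue
        if kind == "simulated":
            table = test_differential(sim_matrices[name])
        elif kind == "matrix":
            table = test_differential(pd.read_csv(e["path"], sep="\t"))
        elif kind == "geo2r":
            table = ingest_geo2r(e["path"], columns=e.get("columns"))
        else:  # lists
            out[name] = ExperimentDE(
                name=name,
                over=frozenset(read_gene_list(e["over"])),
                under=frozenset(read_gene_list(e["under"])),
                universe=universe,
                thresholds=(config.fc_cut, config.p_cut),
            )
            continue
        out[name] = apply_thresholds(table, universe, fc_cut=config.fc_cut,
                                     p_cut=config.p_cut, name=name)
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage of a validated config and return the full report.

    Raises :class:`ConfigurationError` with all validation issues aggregated
    before any computation starts; per-stage failures propagate with their
    stage visible in the message.
    """
    issues = validate_config(config)
    if issues:
        raise ConfigurationError("invalid config:\n- " + "\n- ".join(issues))

    if config.universe_path is not None:
        universe = GeneUniverse.from_file(config.universe_path)
    else:
        universe = make_universe(config.simulation.N,
                                 child_seed(config.master_seed, "simulate"))

    warnings: dict = {}
    experiments = _load_experiments(config, universe, warnings)
    dual_counts = {n: len(x.dual_direction) for n, x in experiments.items()
                   if x.dual_direction}
    if dual_counts:
        warnings["dual_direction_genes"] = dual_counts
        logger.info("dual-direction genes per experiment: %s", dual_counts)
    dropped = {n: x.n_dropped_not_in_universe for n, x in experiments.items()
               if x.n_dropped_not_in_universe}
    if dropped:
        warnings["symbols_dropped_not_in_universe"] = dropped

    records: list[dict] = []
    for c in config.comparisons:
        cname = c.get("name") or _comparison_name(c)
        if c["kind"] == "pairwise":
            comp = directional_suite(
                experiments[c["a"]], experiments[c["b"]], universe,
                n_perm=config.n_perm,
                seed=child_seed(config.master_seed, "comparison", cname),
                alpha=config.alpha,
            )
            for (d_a, d_b) in DirectionalComparison.PAIRS:
                res = comp.results[(d_a, d_b)]
                records.append({
                    "comparison": cname, "type": "pairwise",
                    "experiment_a": comp.name_a, "experiment_b": comp.name_b,
                    "direction_a": d_a, "direction_b": d_b,
                    "significant": comp.significant[(d_a, d_b)],
                    **res.to_dict(),
                })
        else:
            names = list(c["experiments"])
            direction = c["direction"]
            sets = [getattr(experiments[n], direction) for n in names]
            res = exact_multiset_test(sets, universe, names=names)
            shared = sorted(set.intersection(*map(set, sets))) if all(sets) else []
            records.append({
                "comparison": cname, "type": "multiset",
                "experiments": names, "direction": direction,
                "shared_genes": shared,
                **res.to_dict(),
            })

    report = RunReport(
        records=records,
        provenance={
            "config_hash": config.canonical_hash(),
            "master_seed": config.master_seed,
            "n_perm": config.n_perm,
            "fc_cut": config.fc_cut,
            "p_cut": config.p_cut,
            "package_version": _pkg_version,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        warnings=warnings,
    )
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


_TSV_COLUMNS = [
    "comparison", "type", "experiment_a", "experiment_b", "direction_a",
    "direction_b", "experiments", "direction", "set_a_size", "set_b_size",
    "set_sizes", "N", "k", "intersection_size", "union_size", "observed",
    "expected", "fold_enrichment", "jaccard", "null_mean", "null_sd",
    "z_score", "empirical_p", "exact_p", "significant", "n_perm", "seed",
]


def write_report(report: RunReport, outdir) -> dict[str, Path]:
    """Write the JSON report and a flat TSV of all comparison records.

    Field order is stable (sorted keys in JSON, fixed column list in the
    TSV) so that reruns of one config produce byte-identical files apart
    from the provenance timestamp.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    tsv_path = outdir / "comparisons.tsv"
    json_path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))

    rows = []
    for rec in report.records:
        row = {k: rec.get(k) for k in _TSV_COLUMNS}
        if isinstance(row.get("experiments"), list):
            row["experiments"] = ";".join(row["experiments"])
        if isinstance(row.get("set_sizes"), list):
            row["set_sizes"] = ";".join(map(str, row["set_sizes"]))
        rows.append(row)
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    return {"json": json_path, "tsv": tsv_path}
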