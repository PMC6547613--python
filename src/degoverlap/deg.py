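"""Differential-expression calling and directional DEG list construction.

Turns a two-condition log2 expression matrix (or an ingested GEO2R-style
differential-expression export) into per-gene directional lists using the
standard microarray filter: linear fold change strictly greater than a cut
(default 1.5) and unadjusted p-value at most a cut (default 0.05).

Probes collapse to gene symbols with an any-probe-passes rule per direction,
so a gene whose probes disagree in direction can legitimately appear in both
the over- and under-expressed list; such dual-direction genes are counted and
reported, not silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import split_symbols, write_gene_list
from .errors import ConfigurationError, InvalidArgumentError, ParseError
from .synthetic import ExpressionExperiment, GeneUniverse

logger = logging.getLogger(__name__)

META_COLUMNS = ("probe_id", "gene_symbol")


@dataclass
class DETable:
    """Per-probe differential-expression statistics.

    ``frame`` columns: ``probe_id``, ``gene_symbol``, ``log2fc`` (treatment
    minus control), ``fc_linear`` (sign = direction, magnitude = 2^|log2fc|,
    so |fc_linear| >= 1 always), ``p_value`` (unadjusted, in [0, 1] or NaN
    for degenerate rows).
    """

    frame: pd.DataFrame
    dropped: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)


def _fc_linear(log2fc: np.ndarray) -> np.ndarray:
    # sign gives direction, magnitude = 2^|log2fc|; zero log2fc -> +1.
    mag = np.exp2(np.abs(log2fc))
    return np.where(log2fc >= 0, mag, -mag)


def _split_condition_columns(frame: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Infer control/treatment columns from ``<condition>_<replicate>`` names."""
    groups: dict[str, list[str]] = {}
    for col in frame.columns:
        if col in META_COLUMNS:
            continue
        cond = str(col).rsplit("_", 1)[0]
        groups.setdefault(cond, []).append(col)
    if len(groups) != 2:
        raise InvalidArgumentError(
            f"expected exactly 2 conditions in sample columns, found {sorted(groups)}"
        )
    # 'control' (or alphabetically first) is the reference condition.
    names = sorted(groups, key=lambda c: (c.lower() != "control", c))
    return groups[names[0]], groups[names[1]]


def test_differential(
    matrix: pd.DataFrame | ExpressionExperiment,
    control_cols: list[str] | None = None,
    treatment_cols: list[str] | None = None,
) -> DETable:
    """Per-probe Welch t-test on log2 intensities between two conditions.

    ``log2fc`` is mean(treatment) − mean(control); the p-value is from a
    two-sided two-sample Welch t-test on the log2 values. Rows whose values
    are identical in both conditions have zero variance and an undefined
    statistic; their p-value is NaN (and they can never pass a p filter).

    Columns are auto-detected from ``<condition>_<replicate>`` headers when
    not given explicitly; ``control`` is taken as the reference condition.
    """
    if isinstance(matrix, ExpressionExperiment):
        matrix = matrix.frame
    frame = matrix.copy()
    if "probe_id" not in frame.columns:
        raise InvalidArgumentError("matrix must have a 'probe_id' column")
    if "gene_symbol" not in frame.columns:
        frame["gene_symbol"] = frame["probe_id"]
    if control_cols is None or treatment_cols is None:
        control_cols, treatment_cols = _split_condition_columns(frame)
    if len(control_cols) < 2 or len(treatment_cols) < 2:
        raise InvalidArgumentError(
            "each condition needs >= 2 replicates for a p-value "
            f"(got {len(control_cols)} control, {len(treatment_cols)} treatment)"
        )

    for col in [*control_cols, *treatment_cols]:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.loc[bad, "probe_id"].iloc[0]
            raise ParseError(f"non-numeric value in column {col!r}, row {row!r}")
        frame[col] = coerced

    ctrl = frame[control_cols].to_numpy(dtype=float)
    treat = frame[treatment_cols].to_numpy(dtype=float)
    log2fc = treat.mean(axis=1) - ctrl.mean(axis=1)
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # zero-variance rows trip scipy's precision-loss warning; their
        # p-values are overridden explicitly below
        _warnings.filterwarnings("ignore", category=RuntimeWarning,
                                 message="Precision loss occurred")
        result = stats.ttest_ind(treat, ctrl, axis=1, equal_var=False)
    p_value = np.asarray(result.pvalue, dtype=float)
    # Zero within-group variance with a nonzero shift: evidence is exact.
    both_const = (ctrl.std(axis=1) == 0) & (treat.std(axis=1) == 0)
    p_value = np.where(both_const & (log2fc != 0), 0.0, p_value)
    p_value = np.where(both_const & (log2fc == 0), np.nan, p_value)

    out = pd.DataFrame({
        "probe_id": frame["probe_id"].astype(str),
        "gene_symbol": frame["gene_symbol"].astype(str),
        "log2fc": log2fc,
        "fc_linear": _fc_linear(log2fc),
        "p_value": p_value,
    })
    return DETable(out)


@dataclass
class ExperimentDE:
    """Directional DEG lists of one experiment after threshold filtering.

    ``over`` and ``under`` may intersect only when distinct probes of one
    gene pass the filters in opposite directions (dual-direction genes).
    """

    name: str
    over: frozenset[str]
    under: frozenset[str]
    universe: GeneUniverse
    thresholds: tuple[float, float]  # (fc_cut on linear scale, p_cut)
    gene_stats: pd.DataFrame | None = None  # per (gene, direction): best fc, best p
    n_dropped_not_in_universe: int = 0

    @property
    def all_degs(self) -> frozenset[str]:
        return self.over | self.under

    @property
    def dual_direction(self) -> frozenset[str]:
        return self.over & self.under

    def write(self, prefix) -> dict[str, Path]:
        """Write over/under lists, a per-gene TSV summary, and a JSON sidecar."""
        import json

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "over": prefix.with_name(prefix.name + ".over.txt"),
            "under": prefix.with_name(prefix.name + ".under.txt"),
            "summary": prefix.with_name(prefix.name + ".genes.tsv"),
            "sidecar": prefix.with_name(prefix.name + ".json"),
        }
        write_gene_list(self.over, paths["over"])
        write_gene_list(self.under, paths["under"])
        if self.gene_stats is not None:
            self.gene_stats.to_csv(paths["summary"], sep="\t", index=False)
        paths["sidecar"].write_text(json.dumps({
            "name": self.name,
            "fc_cut": self.thresholds[0],
            "p_cut": self.thresholds[1],
            "n_over": len(self.over),
            "n_under": len(self.under),
            "n_dual_direction": len(self.dual_direction),
            "n_dropped_not_in_universe": self.n_dropped_not_in_universe,
        }, indent=1, sort_keys=True))
        return paths


def apply_thresholds(
    table: DETable,
    universe: GeneUniverse,
    fc_cut: float = 1.5,
    p_cut: float = 0.05,
    name: str = "experiment",
) -> ExperimentDE:
    """Filter a DE table into directional gene lists.

    A probe passes iff ``|fc_linear| > fc_cut`` (strict) and
    ``p_value <= p_cut`` (inclusive). Passing probes collapse to gene symbols
    per direction: a gene is over-expressed if any probe passes positively,
    under-expressed if any passes negatively. Symbols outside the universe
    are dropped (counted and logged). ``///``-joined multi-symbol annotations
    contribute every symbol.
    """
    if fc_cut < 1:
        raise InvalidArgumentError(f"fc_cut must be >= 1 (linear scale), got {fc_cut}")
    if not (0 < p_cut <= 1):
        raise InvalidArgumentError(f"p_cut must be in (0, 1], got {p_cut}")

    frame = table.frame
    if frame.empty:
        logger.warning("apply_thresholds(%s): empty DE table, returning empty lists", name)
        return ExperimentDE(name, frozenset(), frozenset(), universe, (fc_cut, p_cut))

    passing = (frame["fc_linear"].abs() > fc_cut) & (frame["p_value"] <= p_cut)
    hits = frame.loc[passing.fillna(False)]

    universe_set = universe.as_set()
    per_direction: dict[str, dict[str, tuple[float, float]]] = {"over": {}, "under": {}}
    dropped: set[str] = set()
    for fc, p, annotation in zip(hits["fc_linear"], hits["p_value"], hits["gene_symbol"]):
        direction = "over" if fc > 0 else "under"
        for sym in split_symbols(annotation):
            if sym not in universe_set:
                dropped.add(sym)
                continue
            best = per_direction[direction].get(sym)
            if best is None or (abs(fc), -p) > (abs(best[0]), -best[1]):
                per_direction[direction][sym] = (fc, p)
    if dropped:
        logger.info("apply_thresholds(%s): dropped %d symbol(s) not in universe",
                    name, len(dropped))

    rows = [
        {"gene_symbol": g, "direction": d, "best_fc_linear": fc, "best_p": p}
        for d in ("over", "under")
        for g, (fc, p) in sorted(per_direction[d].items())
    ]
    gene_stats = pd.DataFrame(rows, columns=["gene_symbol", "direction",
                                             "best_fc_linear", "best_p"])
    return ExperimentDE(
        name=name,
        over=frozenset(per_direction["over"]),
        under=frozenset(per_direction["under"]),
        universe=universe,
        thresholds=(fc_cut, p_cut),
        gene_stats=gene_stats,
        n_dropped_not_in_universe=len(dropped),
    )


# Header spellings seen in GEO2R exports across platforms.
_GEO2R_ALIASES = {
    "probe_id": ("ID", "ID_REF", "probe_id", "ProbeName"),
    "gene_symbol": ("Gene.symbol", "GENE_SYMBOL", "Gene_symbol", "gene_symbol",
                    "Gene.Symbol", "SYMBOL", "GeneSymbol"),
    "log2fc": ("logFC", "log2fc", "log2FoldChange", "LogFC"),
    "p_value": ("P.Value", "p_value", "pvalue", "P-value", "PVAL", "P.value"),
}


def ingest_geo2r(path, columns: dict[str, str] | None = None) -> DETable:
    """Read a GEO2R-style differential-expression export into a :class:`DETable`.

    ``columns`` maps the canonical names ``probe_id`` / ``gene_symbol`` /
    ``log2fc`` / ``p_value`` to file headers; unmapped names are auto-detected
    from standard GEO2R spellings. Rows with a missing symbol or missing
    statistics are dropped and counted.
    """
    raw = pd.read_csv(path, sep=None, engine="python")
    mapping = dict(columns or {})
    for canonical, aliases in _GEO2R_ALIASES.items():
        if canonical in mapping:
            continue
        found = next((a for a in aliases if a in raw.columns), None)
        if found is not None:
            mapping[canonical] = found
    missing = [c for c in ("gene_symbol", "log2fc", "p_value") if c not in mapping]
    if missing:
        raise ConfigurationError(
            f"cannot map mandatory column(s) {missing}; available headers: "
            f"{list(raw.columns)}"
        )
    for canonical, header in mapping.items():
        if header not in raw.columns:
            raise ConfigurationError(
                f"mapped column {header!r} (for {canonical}) not in file; "
                f"available headers: {list(raw.columns)}"
            )

    n_in = len(raw)
    frame = pd.DataFrame({
        "probe_id": (raw[mapping["probe_id"]].astype(str)
                     if "probe_id" in mapping else raw.index.astype(str)),
        "gene_symbol": raw[mapping["gene_symbol"]],
        "log2fc": pd.to_numeric(raw[mapping["log2fc"]], errors="coerce"),
        "p_value": pd.to_numeric(raw[mapping["p_value"]], errors="coerce"),
    })
    symbol_ok = frame["gene_symbol"].notna() & (frame["gene_symbol"].astype(str).str.strip() != "")
    stats_ok = frame["log2fc"].notna() & frame["p_value"].notna()
    frame = frame.loc[symbol_ok & stats_ok].reset_index(drop=True)
    frame["gene_symbol"] = frame["gene_symbol"].astype(str)
    frame["fc_linear"] = _fc_linear(frame["log2fc"].to_numpy())
    frame = frame[["probe_id", "gene_symbol", "log2fc", "fc_linear", "p_value"]]
    n_dropped = n_in - len(frame)
    if n_dropped:
        logger.info("ingest_geo2r(%s): dropped %d row(s) with missing symbol or stats",
                    path, n_dropped)
    return DETable(frame, dropped={"missing_symbol_or_stats": n_dropped})
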