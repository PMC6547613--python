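"""Shared plumbing: seeded RNG streams, symbol normalization, list/GMT I/O."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import numpy as np

_SEP = "\x1f"


def child_seed(master_seed: int, *labels) -> int:
    """Derive a stable 64-bit sub-seed from a master seed and string labels.

    Uses SHA-256 of the label path so the stream assigned to one stage or
    experiment does not move when unrelated stages are added or reordered.
    """
    payload = _SEP.join([str(int(master_seed)), *map(str, labels)])
    digest = hashlib.sha256(payload.encode()).digest()
    return int.from_bytes(digest[:8], "little")


def child_rng(master_seed: int, *labels) -> np.random.Generator:
    """A numpy Generator seeded by :func:`child_seed` of the label path."""
    return np.random.default_rng(np.random.SeedSequence(child_seed(master_seed, *labels)))


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped, upper-cased."""
    return symbol.strip().upper()


def split_symbols(annotation: str) -> list[str]:
    """Split an array-platform annotation into normalized symbols.

    Platform tables annotate some probes with several symbols joined by
    ``///``; each is returned separately. Empty fragments are dropped.
    """
    parts = [normalize_symbol(p) for p in str(annotation).split("///")]
    return [p for p in parts if p]


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list; blank lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        sym = normalize_symbol(line)
        if sym:
            out.append(sym)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line[:80]!r}")
        name, _desc, *members = fields
        sets[name] = [normalize_symbol(m) for m in members if m.strip()]
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path, description: str = "") -> None:
    lines = [
        "\t".join([name, description or name, *sorted(members)])
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
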