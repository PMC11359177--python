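"""Hit counting in protein-protein interaction (PPI) seed networks.

Given PPI edge lists (STRING-export style), a list of seed (disease) genes
and the set of ISM screen hits, these operations count, for each seed, how
many of its network neighbours are predicted targets, and how many distinct
seed networks each target appears in.  Identifier matching is exact and
case-sensitive on gene-symbol strings; alias resolution is an
external-database concern and deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .screen import ScreenHit

__all__ = [
    "EdgeList",
    "SeedReport",
    "load_edges",
    "edge_list_from_pairs",
    "count_hits_per_seed",
    "hit_multiplicity",
    "filter_seeds_by_min_hits",
    "load_ovarian_example",
    "write_seed_reports",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeList:
    """Undirected PPI graph; self-loops removed, pairs stored order-free."""

    graph: nx.Graph

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        if node not in self.graph:
            return set()
        return set(self.graph.neighbors(node))

    def __contains__(self, node: str) -> bool:
        return node in self.graph


@dataclass(frozen=True)
class SeedReport:
    seed_id: str
    hit_interactors: tuple[tuple[str, float], ...]  # (hit_id, snr), snr desc

    @property
    def hit_count(self) -> int:
        return len(self.hit_interactors)


def edge_list_from_pairs(
    pairs: Iterable[tuple[str, str]] | Iterable[tuple[str, str, float]]
) -> EdgeList:
    """Build an EdgeList in memory; self-loops and duplicates are dropped."""
    g = nx.Graph()
    for row in pairs:
        a, b = row[0], row[1]
        if a == b:
            continue
        score = float(row[2]) if len(row) > 2 else None
        g.add_edge(a, b, **({"score": score} if score is not None else {}))
    return EdgeList(g)


def load_edges(path: str | Path, max_neighbors: int | None = None) -> EdgeList:
    """Load a tab-separated edge list ``proteinA  proteinB  [score]``.

    When a score column is present and ``max_neighbors`` is given, only the
    ``max_neighbors`` highest-scoring partners of each first-column protein
    are retained (mirroring the STRING-export cap on interactors shown).
    Duplicate edges and self-loops are dropped with counts logged.
    """
    path = Path(path)
    rows: list[tuple[str, str, float | None]] = []
    has_score = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least two identifiers, got {raw!r}")
        score: float | None = None
        if len(parts) >= 3 and parts[2] != "":
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {parts[2]!r}") from exc
            has_score = True
        rows.append((parts[0].strip(), parts[1].strip(), score))
    if not rows:
        raise ValueError(f"{path}: empty edge list")

    if has_score and max_neighbors is not None:
        by_query: dict[str, list[tuple[str, str, float | None]]] = {}
        for row in rows:
            by_query.setdefault(row[0], []).append(row)
        kept: list[tuple[str, str, float | None]] = []
        for query, qrows in by_query.items():
            qrows.sort(key=lambda r: (-(r[2] if r[2] is not None else float("-inf")), r[1]))
            kept.extend(qrows[:max_neighbors])
        rows = kept

    g = nx.Graph()
    n_self = n_dup = 0
    for a, b, score in rows:
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b, **({"score": score} if score is not None else {}))
    if n_self or n_dup:
        logger.info("%s: dropped %d self-loop(s) and %d duplicate edge(s)", path, n_self, n_dup)
    return EdgeList(g)


def _hit_snr_map(hits: Mapping[str, float] | Iterable[ScreenHit]) -> dict[str, float]:
    if isinstance(hits, Mapping):
        return {str(k): float(v) for k, v in hits.items()}
    return {h.protein_id: h.snr for h in hits}


def count_hits_per_seed(
    seeds: Sequence[str],
    edges: EdgeList,
    hits: Mapping[str, float] | Iterable[ScreenHit],
) -> list[SeedReport]:
    """Intersect each seed's neighbourhood with the hit set.

    The seed itself is never counted as its own interactor.  Seeds absent
    from the edge list are reported with count 0 (warning, not error) so the
    seed-list length is conserved in the output.  Reports are sorted by
    hit_count descending, then seed id.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    snr_by_hit = _hit_snr_map(hits)
    reports: list[SeedReport] = []
    for seed in seeds:
        if seed not in edges:
            logger.warning("seed %s absent from the edge list; reporting 0 hits", seed)
        matched = [
            (n, snr_by_hit[n]) for n in edges.neighbors(seed) if n in snr_by_hit and n != seed
        ]
        matched.sort(key=lambda t: (-t[1], t[0]))
        reports.append(SeedReport(seed, tuple(matched)))
    reports.sort(key=lambda r: (-r.hit_count, r.seed_id))
    return reports


def hit_multiplicity(reports: Sequence[SeedReport]) -> dict[str, tuple[int, list[str]]]:
    """For each hit, the number of distinct seed networks containing it.

    Returns ``hit_id -> (count, alphabetically sorted seed list)``; the
    mapping is invariant under permutation of the input reports.
    """
    seeds_by_hit: dict[str, set[str]] = {}
    for rep in reports:
        for hit_id, _ in rep.hit_interactors:
            seeds_by_hit.setdefault(hit_id, set()).add(rep.seed_id)
    return {h: (len(s), sorted(s)) for h, s in sorted(seeds_by_hit.items())}


def filter_seeds_by_min_hits(reports: Sequence[SeedReport], k: int) -> list[SeedReport]:
    """Reports whose hit_count is at least ``k``, input order preserved."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return [r for r in reports if r.hit_count >= k]


def load_ovarian_example() -> tuple[list[str], EdgeList, dict[str, float]]:
    """Bundled worked example: ISM-predicted ruthenium-complex targets inside
    STRING neighbourhoods of ovarian-neoplasm (HPO HP:0100615) genes.

    Returns (seed list, edge list, hit -> S/N map) reconstructed from the
    published per-network membership table.
    """
    with resources.as_file(
        resources.files("spectarget.data") / "ovarian_hpo_ism_targets.tsv"
    ) as p:
        rows = []
        for raw in Path(p).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            seed, hit, snr = line.split("\t")
            rows.append((seed, hit, float(snr)))
    seeds = sorted({seed for seed, _, _ in rows})
    edges = edge_list_from_pairs([(seed, hit) for seed, hit, _ in rows])
    hit_snr = {hit: snr for _, hit, snr in rows}
    return seeds, edges, hit_snr


def write_seed_reports(
    reports: Sequence[SeedReport], path: str | Path
) -> None:
    """TSV mirroring the published layout: seed, hit, snr, multiplicity."""
    mult = hit_multiplicity(reports)
    lines = ["seed\thit\tsnr\tmultiplicity"]
    for rep in reports:
        if not rep.hit_interactors:
            lines.append(f"{rep.seed_id}\t\t\t")
            continue
        for hit_id, hsnr in rep.hit_interactors:
            lines.append(f"{rep.seed_id}\t{hit_id}\t{hsnr:.6g}\t{mult[hit_id][0]}")
    Path(path).write_text("\n".join(lines) + "\n")
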