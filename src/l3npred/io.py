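"""Edge-list ingestion and serialization.

Raw PPI edge lists are messy: the same interaction may appear in both
directions (a b and b a), duplicated across evidence lines, or as a
self-interaction (SIP).  :func:`load_edge_list` applies the standard
cleaning — collapse directional duplicates, drop exact duplicates, remove
self-loops (optional) — and returns the cleaned network together with a
:class:`DatasetManifest` whose counts reconcile exactly:

    raw = kept + duplicates_collapsed + sips_removed + filtered_out + malformed

:func:`write_edge_list` emits a canonical edge list (lexicographic pairs,
sorted lines) so equal graphs serialize to byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .graph import PPINetwork

__all__ = ["DatasetManifest", "load_edge_list", "write_edge_list"]


@dataclass
class DatasetManifest:
    """Cleaning provenance for one loaded edge list."""

    source: str
    raw_records: int = 0
    duplicates_collapsed: int = 0  # directional + exact repeats
    sips_removed: int = 0
    filtered_out: int = 0
    malformed: int = 0
    kept_edges: int = 0
    nodes: int = 0
    options: dict = field(default_factory=dict)

    def check(self) -> None:
        total = (
            self.kept_edges
            + self.duplicates_collapsed
            + self.sips_removed
            + self.filtered_out
            + self.malformed
        )
        if total != self.raw_records:
            raise AssertionError(
                f"manifest does not reconcile: {total} accounted vs {self.raw_records} raw"
            )


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ("," if "," in line else None)  # type: ignore[return-value]


def _looks_like_header(fields: list[str]) -> bool:
    lowered = [f.strip().lower() for f in fields[:2]]
    headerish = {"node", "nodea", "nodeb", "protein", "proteina", "proteinb",
                 "source", "target", "interactor", "interactora", "interactorb",
                 "id1", "id2", "gene1", "gene2"}
    return any(f in headerish for f in lowered)


def load_edge_list(
    path: str,
    delimiter: str | None = None,
    drop_sips: bool = True,
    column_filter: tuple[int, set[str]] | None = None,
    skip_header: bool | None = None,
) -> tuple[PPINetwork, DatasetManifest]:
    """Load a two-column edge list with cleaning and accounting.

    Parameters
    ----------
    delimiter
        Field separator; sniffed from the first data line (tab, then comma,
        then whitespace) when None.
    drop_sips
        Remove self-interaction rows (a a).  They are counted either way.
    column_filter
        ``(column_index, accepted_values)``: keep only rows whose field at
        that index is in the accepted set (generic stand-in for
        database-specific annotation filters).
    skip_header
        Force-skip (True) or force-keep (False) the first line; None uses a
        name-based heuristic.

    Raises
    ------
    ValueError
        If no edges survive cleaning.
    """
    manifest = DatasetManifest(
        source=str(path),
        options={
            "delimiter": delimiter,
            "drop_sips": drop_sips,
            "column_filter": None if column_filter is None else
                [column_filter[0], sorted(column_filter[1])],
        },
    )
    net = PPINetwork()
    seen: set[frozenset[str]] = set()
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if delimiter is None:
                delimiter = _sniff_delimiter(line)
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f.strip() for f in fields]
            if first:
                first = False
                skip = skip_header if skip_header is not None else _looks_like_header(fields)
                if skip:
                    continue
            manifest.raw_records += 1
            if len(fields) < 2 or not fields[0] or not fields[1]:
                manifest.malformed += 1
                continue
            if column_filter is not None:
                idx, accepted = column_filter
                if idx >= len(fields) or fields[idx] not in accepted:
                    manifest.filtered_out += 1
                    continue
            a, b = fields[0], fields[1]
            if a == b:
                manifest.sips_removed += 1
                if not drop_sips:
                    # the protein is kept as a node; a self-loop has no
                    # representation in a simple graph either way
                    net.add_node(a)
                continue
            key = frozenset((a, b))
            if key in seen:
                manifest.duplicates_collapsed += 1
                continue
            seen.add(key)
            net.add_edge(a, b)
            manifest.kept_edges += 1
    if net.edge_count == 0:
        raise ValueError(f"no edges survived cleaning of {path!r}")
    manifest.nodes = len(net)
    manifest.check()
    return net, manifest


def write_edge_list(net: PPINetwork, path: str) -> None:
    """Write one edge per line, tab-separated, lexicographic pairs in sorted
    line order — byte-stable across graphs with equal edge sets."""
    if net.edge_count == 0:
        raise ValueError("refusing to write an empty network")
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
    with open(path, "w") as fh:
        for a, b in net.edges():  # already sorted canonically
            fh.write(f"{a}\t{b}\n")
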