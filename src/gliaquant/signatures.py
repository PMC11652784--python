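"""Fold-change filtering, Venn set intersection and perturbagen-score screens.

Tabular inputs are plain CSV:

* a gene fold table with columns ``gene, group, fold`` — fold is the signed
  expression ratio, positive for upregulation and negative-mirrored for
  downregulation (a 2.7-fold decrease is stored as -2.7, not 0.37);
* a perturbagen score table with columns ``name, kind, group, score`` where
  kind is ``PCL`` (perturbagen class, a mechanism-of-action group) or ``PC``
  (perturbagen compound) and score is a connectivity score in [-100, 100]
  (100 = identical signature, -100 = opposite).

Three screening conventions, matching the upstream analyses these tables
come from: fold cutoffs are inclusive (|fold| >= 2 passes at cutoff 2);
score thresholds are strict ("exceeding 80.0" keeps score > 80); gene
symbols are matched case-insensitively with whitespace stripped, through a
small alias table of known typographical variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "GENE_ALIASES",
    "normalize_gene",
    "VennResult",
    "filter_by_fold",
    "intersect_sets",
    "filter_scores",
    "shared_annotations",
    "parse_common_group",
    "format_common_group",
    "load_packaged_table",
    "packaged_gene_sets",
]

# Typographical variants (running-text spelling -> table symbol); keys are
# casefolded with internal whitespace removed.
GENE_ALIASES: dict[str, str] = {
    "carl3": "Calr3",
    "r1f": "Rlf",
    "rio1": "Riok1",
    "igbo-v7183": "Igh-V7183",
    "atpla2": "Atp1a2",
    "parkar1b": "Prkar1b",
}


def normalize_gene(name: str) -> str:
    """Canonical gene symbol: strip whitespace, resolve known aliases.

    Matching is case-insensitive; the returned symbol keeps the canonical
    capitalization of the first form seen (alias targets are returned with
    their table capitalization).
    """
    cleaned = "".join(str(name).split())
    if not cleaned:
        raise ValueError("empty gene symbol")
    return GENE_ALIASES.get(cleaned.casefold(), cleaned)


def _gene_key(name: str) -> str:
    return normalize_gene(name).casefold()


@dataclass
class VennResult:
    """Exact disjoint Venn regions over up to a handful of groups.

    ``regions`` maps a frozenset of group names to the sorted elements found
    in exactly those groups; ``group_order`` preserves the caller's group
    ordering for annotation output.
    """

    group_order: list[str]
    regions: dict[frozenset, list[str]] = field(default_factory=dict)

    @property
    def region_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def count(self, *groups: str) -> int:
        """Elements in *exactly* this subset of groups (a disjoint region)."""
        return len(self.regions.get(frozenset(groups), []))

    def membership(self) -> dict[str, tuple[str, ...]]:
        """Element -> ordered tuple of containing groups."""
        out = {}
        for key, elems in self.regions.items():
            ordered = tuple(g for g in self.group_order if g in key)
            for e in elems:
                out[e] = ordered
        return out

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def filter_by_fold(
    records: pd.DataFrame,
    up_cut: float = 2.0,
    down_cut: float = -2.0,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-group up/down gene sets at inclusive signed-fold cutoffs.

    Returns ``(up_sets, down_sets)``: up = genes with fold >= up_cut, down =
    genes with fold <= down_cut.  ``records`` needs columns gene, group,
    fold.
    """
    if up_cut < 1 or down_cut > -1:
        raise ValueError(f"cutoffs must satisfy up_cut >= 1 and down_cut <= -1, got {up_cut}, {down_cut}")
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for _, row in records.iterrows():
        gene = normalize_gene(row["gene"])
        group = str(row["group"])
        fold = float(row["fold"])
        up.setdefault(group, set())
        down.setdefault(group, set())
        if fold >= up_cut:
            up[group].add(gene)
        elif fold <= down_cut:
            down[group].add(gene)
    return up, down


def intersect_sets(sets: dict[str, set[str]]) -> VennResult:
    """Partition the union of the given sets into exact disjoint Venn regions."""
    if not sets:
        raise ValueError("need at least one group")
    keyed = {g: {_gene_key(e): normalize_gene(e) for e in elems} for g, elems in sets.items()}
    universe: dict[str, str] = {}
    for mapping in keyed.values():
        universe.update(mapping)
    regions: dict[frozenset, list[str]] = {}
    for key, symbol in universe.items():
        member = frozenset(g for g, mapping in keyed.items() if key in mapping)
        regions.setdefault(member, []).append(symbol)
    for elems in regions.values():
        elems.sort()
    return VennResult(group_order=list(sets), regions=regions)


def filter_scores(
    entries: pd.DataFrame,
    threshold: float,
    kind: str | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], int]]:
    """Retain entries with score strictly above ``threshold``.

    Returns the retained rows plus counts per (group, kind).  ``kind``
    optionally restricts to PCL or PC rows first.
    """
    if not -100 <= threshold <= 100:
        raise ValueError(f"threshold must be in [-100, 100], got {threshold}")
    bad = entries[(entries["score"] < -100) | (entries["score"] > 100)]
    if not bad.empty:
        raise ValueError("scores outside [-100, 100]")
    df = entries if kind is None else entries[entries["kind"] == kind]
    kept = df[df["score"] > threshold].copy()
    counts = {
        (str(g), str(k)): int(n)
        for (g, k), n in kept.groupby(["group", "kind"], sort=True).size().items()
    }
    return kept, counts


def parse_common_group(annotation: str) -> tuple[str, ...]:
    """Parse a common-group annotation like ``"A1, S1, C1"`` (also ``;``)."""
    if annotation is None or (isinstance(annotation, float) and pd.isna(annotation)):
        return ()
    tokens = str(annotation).replace(";", ",").split(",")
    return tuple(t.strip() for t in tokens if t.strip())


def format_common_group(groups: tuple[str, ...] | list[str]) -> str:
    return ", ".join(groups)


def shared_annotations(venn: VennResult) -> pd.DataFrame:
    """Element -> common-group annotation string table.

    Groups in each annotation follow ``venn.group_order``; an element found
    in a single group is annotated with that group's label alone.
    """
    membership = venn.membership()
    rows = [
        {"element": e, "common_group": format_common_group(membership[e])}
        for e in sorted(membership)
    ]
    return pd.DataFrame(rows, columns=["element", "common_group"])


_PACKAGED = {
    "pcl_scores": "pcl_scores.csv",
    "upregulated_genes": "upregulated_genes.csv",
    "downregulated_genes": "downregulated_genes.csv",
}


def load_packaged_table(name: str) -> pd.DataFrame:
    """Load one of the packaged screening tables.

    ``pcl_scores``: perturbagen-class connectivity scores per comparison
    group (D4, A1, S1, C1), with their shared-group annotations.
    ``upregulated_genes`` / ``downregulated_genes``: genes two-fold up/down
    in the D4 comparison with the erinacine-treatment groups sharing each
    change annotated in ``common_group``.
    """
    if name not in _PACKAGED:
        raise KeyError(f"unknown packaged table {name!r}; options: {sorted(_PACKAGED)}")
    with resources.files("gliaquant.data").joinpath(_PACKAGED[name]).open() as fh:
        return pd.read_csv(fh)


def packaged_gene_sets(name: str, groups: list[str] = ["A1", "S1", "C1"]) -> dict[str, set[str]]:
    """Build per-group gene sets from a packaged gene table's annotations.

    Each row's gene belongs to its ``group`` column (D4) and to every group
    named in its ``common_group`` annotation; the returned map covers the
    requested groups only.
    """
    df = load_packaged_table(name)
    sets: dict[str, set[str]] = {g: set() for g in groups}
    for _, row in df.iterrows():
        gene = normalize_gene(row["gene"])
        members = set(parse_common_group(row.get("common_group"))) | {str(row["group"])}
        for g in groups:
            if g in members:
                sets[g].add(gene)
    return sets
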