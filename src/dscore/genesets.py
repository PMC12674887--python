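"""Gene sets, the curated regulator panel, and GMT input/output.

Gene symbols are matched case-sensitively and exactly; no alias resolution is
attempted. The curated panel ships as package data (``data/core_panel.tsv``)
so alternative panels can be supplied through the same loader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "RegulatorPanel",
    "GmtParseError",
    "PanelDataError",
    "PanelConflictError",
    "read_gmt",
    "write_gmt",
    "load_core_panel",
    "load_panel_tsv",
    "extend_panel",
]


class GmtParseError(ValueError):
    """A GMT line could not be parsed."""


class PanelDataError(ValueError):
    """Bundled or user-supplied panel data is corrupted."""


class PanelConflictError(ValueError):
    """A gene would end up in both the promoter and suppressor set."""

    def __init__(self, genes: Sequence[str]):
        self.genes = tuple(sorted(genes))
        super().__init__(
            "genes present in both promoter and suppressor sets: " + ", ".join(self.genes)
        )


@dataclass(frozen=True)
class GeneSet:
    """An ordered collection of unique gene symbols with a name.

    Parameters
    ----------
    name : str
        Short identifier for the set.
    genes : tuple of str
        Unique, non-empty gene symbols; insertion order is preserved.
    description : str, optional
        Free-text description (GMT column two).
    """

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r}: genes must be non-empty")
        if any((not isinstance(g, str)) or g == "" for g in genes):
            raise ValueError(f"gene set {self.name!r}: symbols must be non-empty strings")
        if len(set(genes)) != len(genes):
            seen: set[str] = set()
            dups = sorted({g for g in genes if g in seen or seen.add(g)})  # type: ignore[func-returns-value]
            raise ValueError(f"gene set {self.name!r}: duplicate symbols {dups}")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersect(self, symbols: Iterable[str]) -> tuple[str, ...]:
        """Genes of this set present in `symbols`, in set order."""
        universe = set(symbols)
        return tuple(g for g in self.genes if g in universe)


@dataclass(frozen=True)
class RegulatorPanel:
    """A promoter gene set and a suppressor gene set under one label."""

    promoters: GeneSet
    suppressors: GeneSet
    label: str = "core"

    def __post_init__(self) -> None:
        overlap = set(self.promoters.genes) & set(self.suppressors.genes)
        if overlap:
            raise PanelConflictError(sorted(overlap))

    @property
    def genes(self) -> tuple[str, ...]:
        return self.promoters.genes + self.suppressors.genes

    def __len__(self) -> int:
        return len(self.promoters) + len(self.suppressors)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (tab-separated: name, description, genes...).

    Duplicate genes within a line are dropped with a logged warning. Lines with
    fewer than three fields raise :class:`GmtParseError` naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g != ""]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s: line %d (%s): %d duplicate gene(s) removed",
                    path, lineno, name, len(genes) - len(deduped),
                )
            sets.append(GeneSet(name=name, genes=tuple(deduped), description=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT (UTF-8, no quoting)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def load_panel_tsv(path: str | Path, label: str = "custom") -> RegulatorPanel:
    """Load a panel from a two-column TSV (gene, role in {promoter, suppressor})."""
    promoters: list[str] = []
    suppressors: list[str] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "role"]:
            raise PanelDataError(f"{path}: expected header 'gene\\trole', got {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise PanelDataError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
            gene, role = fields
            if role == "promoter":
                promoters.append(gene)
            elif role == "suppressor":
                suppressors.append(gene)
            else:
                raise PanelDataError(f"{path}: line {lineno}: unknown role {role!r}")
    if not promoters or not suppressors:
        raise PanelDataError(f"{path}: panel must contain both promoters and suppressors")
    return RegulatorPanel(
        promoters=GeneSet("promoters", tuple(promoters), "panel promoter set"),
        suppressors=GeneSet("suppressors", tuple(suppressors), "panel suppressor set"),
        label=label,
    )


def load_core_panel() -> RegulatorPanel:
    """Load the bundled curated regulator panel (9 promoters, 34 suppressors)."""
    ref = resources.files("dscore").joinpath("data/core_panel.tsv")
    try:
        with resources.as_file(ref) as path:
            panel = load_panel_tsv(path, label="core")
    except (OSError, ValueError) as exc:
        raise PanelDataError(f"bundled core panel could not be loaded: {exc}") from exc
    if len(panel.promoters) != 9 or len(panel.suppressors) != 34:
        raise PanelDataError(
            "bundled core panel is corrupted: expected 9 promoters and 34 suppressors, "
            f"found {len(panel.promoters)} and {len(panel.suppressors)}"
        )
    return panel


def _as_genes(candidates: GeneSet | Iterable[str] | None) -> tuple[str, ...]:
    if candidates is None:
        return ()
    if isinstance(candidates, GeneSet):
        return candidates.genes
    return tuple(dict.fromkeys(candidates))


def extend_panel(
    core: RegulatorPanel,
    cand_promoters: GeneSet | Iterable[str] | None = None,
    cand_suppressors: GeneSet | Iterable[str] | None = None,
    label: str = "plus",
) -> RegulatorPanel:
    """Union candidate genes into the core panel's promoter/suppressor sets.

    The union never double-counts genes already in the core panel. A gene that
    would land in both merged sets raises :class:`PanelConflictError` listing
    the offenders.
    """
    new_promoters = tuple(dict.fromkeys(core.promoters.genes + _as_genes(cand_promoters)))
    new_suppressors = tuple(dict.fromkeys(core.suppressors.genes + _as_genes(cand_suppressors)))
    overlap = set(new_promoters) & set(new_suppressors)
    if overlap:
        raise PanelConflictError(sorted(overlap))
    return RegulatorPanel(
        promoters=GeneSet("promoters", new_promoters, core.promoters.description),
        suppressors=GeneSet("suppressors", new_suppressors, core.suppressors.description),
        label=label,
    )
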