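"""Line x QTL presence/absence panels for pyramiding experiments.

A *panel* couples QTL locus metadata with a set of lines, each carrying a
subset of donor substitution segments in an otherwise isogenic recipient
background (HJX74 in the packaged rice dataset).  Lines are grouped by the
number of stacked QTLs ("1QL" ... "6QL"); the recipient itself is the
zero-QTL control.
"""

from __future__ import annotations

import io
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "QtlLocus",
    "PyramidLine",
    "GenotypePanel",
    "GenotypeError",
    "read_genotype_table",
    "write_genotype_table",
    "read_qtl_metadata",
    "lines_by_group",
    "split_by_focal_locus",
]

DONOR_SPECIES = ("sativa", "glaberrima", "glumaepatula")

#: QTL name suffix -> donor species (first three letters of the species name)
SUFFIX_TO_DONOR = {"sat": "sativa", "gla": "glaberrima", "glu": "glumaepatula"}

#: Presence/absence cell tokens accepted by default.  Plain hyphen, true
#: minus (U+2212) and en dash (U+2013) all mean "absent": published tables
#: are inconsistent about which dash they print.
TRUE_TOKENS = frozenset({"+", "1", "TRUE", "True", "true"})
FALSE_TOKENS = frozenset({"-", "−", "–", "0", "FALSE", "False", "false"})

MAX_PYRAMID_SIZE = 6


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype input."""


@dataclass(frozen=True)
class QtlLocus:
    """A QTL resident on one donor substitution segment.

    ``linked_group`` names loci that co-reside on a single segment in some
    source line (e.g. the two loci on A35's segment) and therefore cannot
    always be separated experimentally.
    """

    name: str
    donor_species: str
    chromosome_tag: str | None = None
    linked_group: str | None = None
    known_additive_effect: float | None = None

    def __post_init__(self) -> None:
        if self.donor_species not in DONOR_SPECIES:
            raise GenotypeError(
                f"unknown donor species {self.donor_species!r} for locus "
                f"{self.name!r}; expected one of {DONOR_SPECIES}"
            )
        suffix = self.name.rsplit("-", 1)[-1] if "-" in self.name else None
        if suffix in SUFFIX_TO_DONOR and SUFFIX_TO_DONOR[suffix] != self.donor_species:
            raise GenotypeError(
                f"locus {self.name!r}: name suffix -{suffix} implies donor "
                f"{SUFFIX_TO_DONOR[suffix]!r} but metadata says "
                f"{self.donor_species!r}"
            )

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "QtlLocus":
        """Build a locus inferring the donor from the name suffix."""
        suffix = name.rsplit("-", 1)[-1] if "-" in name else ""
        if suffix not in SUFFIX_TO_DONOR:
            raise GenotypeError(
                f"cannot infer donor species from locus name {name!r}; "
                "expected a -sat/-gla/-glu suffix"
            )
        return cls(name=name, donor_species=SUFFIX_TO_DONOR[suffix], **kwargs)


@dataclass
class PyramidLine:
    """One line's QTL complement: an ordered locus -> presence mapping."""

    line_id: str
    presence: "OrderedDict[str, bool]"
    is_control: bool = False

    def __post_init__(self) -> None:
        self.presence = OrderedDict(self.presence)
        if self.is_control and self.qtl_count != 0:
            raise GenotypeError(
                f"control line {self.line_id!r} carries "
                f"{self.qtl_count} QTLs; expected 0"
            )

    @property
    def qtl_count(self) -> int:
        return sum(bool(v) for v in self.presence.values())

    @property
    def loci_present(self) -> tuple[str, ...]:
        return tuple(name for name, v in self.presence.items() if v)

    @property
    def group(self) -> str:
        """Group label: ``control`` for 0 QTLs, else ``{n}QL``."""
        n = self.qtl_count
        return "control" if n == 0 else f"{n}QL"

    def has(self, locus: str) -> bool:
        return bool(self.presence.get(locus, False))


@dataclass
class GenotypePanel:
    """A validated collection of loci and lines sharing one locus order."""

    loci: list[QtlLocus]
    lines: list[PyramidLine]
    max_pyramid_size: int = MAX_PYRAMID_SIZE

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise GenotypeError("duplicate locus names in panel")
        ids = [ln.line_id for ln in self.lines]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeError(f"duplicate line_id(s): {dupes}")
        name_set = set(names)
        for ln in self.lines:
            if set(ln.presence) != name_set:
                raise GenotypeError(
                    f"line {ln.line_id!r} presence vector does not index the "
                    "panel's loci exactly"
                )
            if ln.qtl_count > self.max_pyramid_size:
                raise GenotypeError(
                    f"line {ln.line_id!r} stacks {ln.qtl_count} QTLs; the "
                    f"panel allows at most {self.max_pyramid_size}"
                )

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus(self, name: str) -> QtlLocus:
        for l in self.loci:
            if l.name == name:
                return l
        raise GenotypeError(f"unknown locus {name!r}")

    def line(self, line_id: str) -> PyramidLine:
        for ln in self.lines:
            if ln.line_id == line_id:
                return ln
        raise GenotypeError(f"unknown line {line_id!r}")

    @property
    def controls(self) -> list[PyramidLine]:
        return [ln for ln in self.lines if ln.qtl_count == 0]

    @property
    def non_control_lines(self) -> list[PyramidLine]:
        return [ln for ln in self.lines if ln.qtl_count > 0]

    def single_qtl_lines(self) -> dict[str, list[PyramidLine]]:
        """Map locus -> 1-QTL lines carrying it (the SSSL inventory)."""
        out: dict[str, list[PyramidLine]] = {}
        for ln in self.lines:
            if ln.qtl_count == 1:
                out.setdefault(ln.loci_present[0], []).append(ln)
        return out

    def presence_frame(self) -> pd.DataFrame:
        """Boolean line x locus matrix (line_id index, locus columns)."""
        data = {ln.line_id: [ln.presence[n] for n in self.locus_names] for ln in self.lines}
        return pd.DataFrame.from_dict(data, orient="index", columns=self.locus_names)


def _normalize_token(cell: str, true_tokens, false_tokens, where: str) -> bool:
    tok = str(cell).strip()
    if tok in true_tokens:
        return True
    if tok in false_tokens:
        return False
    raise GenotypeError(f"unknown presence token {tok!r} at {where}")


def read_genotype_table(
    path: str | Path | io.TextIOBase,
    *,
    sep: str | None = None,
    true_tokens: Iterable[str] = TRUE_TOKENS,
    false_tokens: Iterable[str] = FALSE_TOKENS,
    metadata: Mapping[str, QtlLocus] | None = None,
    control_ids: Iterable[str] = ("HJX74",),
    max_pyramid_size: int = MAX_PYRAMID_SIZE,
) -> GenotypePanel:
    """Read a line x locus presence table into a :class:`GenotypePanel`.

    The file has a header of locus names, a leading ``line_id`` column and an
    optional second ``group`` column (cross-checked against the QTL count
    when present).  ``sep`` defaults to tab for ``.tsv`` and comma otherwise.
    Donor species are taken from ``metadata`` when given, else inferred from
    the -sat/-gla/-glu name suffix.
    """
    true_tokens, false_tokens = frozenset(true_tokens), frozenset(false_tokens)
    if isinstance(path, (str, Path)):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"genotype table not found: {p}")
        if sep is None:
            sep = "\t" if p.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
        text = p.read_text(encoding="utf-8")
    else:
        text = path.read()
        sep = sep or ","

    rows = [line for line in text.splitlines() if line.strip() and not line.lstrip().startswith("#")]
    if len(rows) < 2:
        raise GenotypeError("genotype table has no data rows")
    header = [h.strip() for h in rows[0].split(sep)]
    if len(header) < 2:
        raise GenotypeError("genotype table header must name at least one locus")
    has_group = len(header) > 1 and header[1].lower() == "group"
    locus_names = header[2:] if has_group else header[1:]
    if not locus_names:
        raise GenotypeError("genotype table header names no loci")

    loci = []
    for name in locus_names:
        if metadata is not None and name in metadata:
            loci.append(metadata[name])
        else:
            loci.append(QtlLocus.from_name(name))

    control_ids = set(control_ids)
    lines: list[PyramidLine] = []
    for idx, raw in enumerate(rows[1:], start=1):
        cells = [c.strip() for c in raw.split(sep)]
        if len(cells) != len(header):
            raise GenotypeError(
                f"ragged row {idx}: {len(cells)} cells, header has {len(header)}"
            )
        line_id = cells[0]
        group_cell = cells[1] if has_group else None
        values = cells[2:] if has_group else cells[1:]
        presence = OrderedDict(
            (name, _normalize_token(tok, true_tokens, false_tokens, f"row {idx} ({line_id}), column {name}"))
            for name, tok in zip(locus_names, values)
        )
        ln = PyramidLine(line_id, presence, is_control=line_id in control_ids)
        if group_cell not in (None, ""):
            if group_cell != ln.group:
                raise GenotypeError(
                    f"row {idx} ({line_id}): declared group {group_cell!r} "
                    f"but presence vector implies {ln.group!r}"
                )
        lines.append(ln)

    return GenotypePanel(loci=loci, lines=lines, max_pyramid_size=max_pyramid_size)


def write_genotype_table(
    panel: GenotypePanel,
    path: str | Path,
    *,
    sep: str = ",",
    true_token: str = "+",
    false_token: str = "-",
    include_group: bool = True,
) -> None:
    """Write a panel back to the CSV/TSV dialect ``read_genotype_table`` reads."""
    lines_out = []
    header = ["line_id"] + (["group"] if include_group else []) + panel.locus_names
    lines_out.append(sep.join(header))
    for ln in panel.lines:
        cells = [ln.line_id] + ([ln.group] if include_group else [])
        cells += [true_token if ln.presence[n] else false_token for n in panel.locus_names]
        lines_out.append(sep.join(cells))
    Path(path).write_text("\n".join(lines_out) + "\n", encoding="utf-8")


def read_qtl_metadata(path: str | Path) -> dict[str, QtlLocus]:
    """Read locus metadata (TSV: name, donor_species, optional chromosome_tag,
    linked_group, known_additive_effect) into a name -> locus mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "name" not in df.columns or "donor_species" not in df.columns:
        raise GenotypeError("metadata needs 'name' and 'donor_species' columns")
    out: dict[str, QtlLocus] = {}
    for _, row in df.iterrows():
        eff = row.get("known_additive_effect")
        out[row["name"]] = QtlLocus(
            name=row["name"],
            donor_species=row["donor_species"],
            chromosome_tag=row.get("chromosome_tag") if pd.notna(row.get("chromosome_tag")) else None,
            linked_group=row.get("linked_group") if pd.notna(row.get("linked_group")) else None,
            known_additive_effect=float(eff) if eff is not None and pd.notna(eff) else None,
        )
    return out


def lines_by_group(panel: GenotypePanel) -> "OrderedDict[str, list[PyramidLine]]":
    """Partition non-control lines by QTL count, ordered 1QL..nQL.

    Empty groups are omitted, so a panel holding only the control maps to an
    empty dict.
    """
    out: OrderedDict[str, list[PyramidLine]] = OrderedDict()
    for n in range(1, panel.max_pyramid_size + 1):
        members = [ln for ln in panel.non_control_lines if ln.qtl_count == n]
        if members:
            out[f"{n}QL"] = members
    return out


def split_by_focal_locus(
    panel: GenotypePanel,
    focal: str,
    groups: Sequence[str] | None = None,
) -> "OrderedDict[str, tuple[list[PyramidLine], list[PyramidLine]]]":
    """Within each group, split lines into (with focal locus, without).

    ``groups`` defaults to every non-empty pyramid group.  The two parts are
    a partition: ``len(with) + len(without)`` equals the group size.
    """
    panel.locus(focal)  # raises for unknown names
    grouped = lines_by_group(panel)
    if groups is None:
        groups = list(grouped)
    out: OrderedDict[str, tuple[list[PyramidLine], list[PyramidLine]]] = OrderedDict()
    for g in groups:
        members = grouped.get(g, [])
        with_ = [ln for ln in members if ln.has(focal)]
        without = [ln for ln in members if not ln.has(focal)]
        out[g] = (with_, without)
    return out
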