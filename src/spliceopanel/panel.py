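"""Reference spliceosomal-protein panel: loading, paralogue collapsing, summaries.

The panel is an inventory of proteins, each placed in one functional
category (snRNP sub-complexes, stage-specific sub-stages, SR/hnRNP/
pre-mRNA-binding, miscellaneous).  Sets of paralogues may be collapsed to a
single representative entry that retains every member sequence, so that a
homology hit to any member satisfies the entry.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

# Categories of group (i): snRNP and non-snRNP core proteins.
SNRNP_CATEGORIES: tuple[str, ...] = (
    "Sm/LSm",
    "U1",
    "U2-related",
    "U4/U5/U6",
    "NTC/NTR/IBC",
    "RES",
    "EJC/TREX",
    "ATPase",
    "CBC",
    "LDE",
)

STAGE_PREFIX = "stage-specific:"

OTHER_CATEGORIES: tuple[str, ...] = ("SR", "hnRNP", "pre-mRNA-binding", "miscellaneous")

_AA = set("ACDEFGHIKLMNPQRSTVWYX")

MANIFEST_COLUMNS = ("id", "name", "category", "paralogue_group")


def is_valid_category(category: str) -> bool:
    if category in SNRNP_CATEGORIES or category in OTHER_CATEGORIES:
        return True
    return category.startswith(STAGE_PREFIX) and len(category) > len(STAGE_PREFIX)


@dataclass(frozen=True)
class PanelEntry:
    """One panel protein (possibly a collapsed paralogue group)."""

    id: str
    name: str
    category: str
    paralogue_group: str | None = None
    sequence: str = "X"
    #: (member id, member sequence) pairs; singleton unless collapsed.
    members: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not is_valid_category(self.category):
            raise ValueError(f"invalid category {self.category!r} for entry {self.id!r}")
        bad = set(self.sequence.upper()) - _AA
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in entry {self.id!r}")
        if not self.members:
            object.__setattr__(self, "members", ((self.id, self.sequence),))

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(mid for mid, _ in self.members)


@dataclass
class Panel:
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.id in seen:
                raise ValueError(f"duplicate entry: {e.id!r}")
            seen.add(e.id)

    @property
    def groups(self) -> dict[str, list[str]]:
        """Map paralogue-group token -> member entry ids (pre-collapse view)."""
        out: dict[str, list[str]] = {}
        for e in self.entries:
            if e.paralogue_group:
                out.setdefault(e.paralogue_group, []).append(e.id)
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, entry_id: str) -> PanelEntry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        payload = [
            {
                "id": e.id,
                "name": e.name,
                "category": e.category,
                "paralogue_group": e.paralogue_group,
                "sequence": e.sequence,
                "members": list(map(list, e.members)),
            }
            for e in self.entries
        ]
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Panel":
        entries = [
            PanelEntry(
                id=d["id"],
                name=d["name"],
                category=d["category"],
                paralogue_group=d.get("paralogue_group"),
                sequence=d["sequence"],
                members=tuple((m[0], m[1]) for m in d.get("members", [])),
            )
            for d in json.loads(text)
        ]
        return cls(entries)


@dataclass(frozen=True)
class PanelSummary:
    counts: Mapping[str, int]
    total: int

    @property
    def snrnp_subtotal(self) -> int:
        """Subtotal of group (i): the ten snRNP/non-snRNP core categories."""
        return sum(self.counts.get(c, 0) for c in SNRNP_CATEGORIES)

    @property
    def stage_specific_subtotal(self) -> int:
        return sum(n for c, n in self.counts.items() if c.startswith(STAGE_PREFIX))

    @property
    def group_totals(self) -> dict[str, int]:
        return {
            "snRNP": self.snrnp_subtotal,
            "stage-specific": self.stage_specific_subtotal,
            "SR/hnRNP/pre-mRNA-binding": sum(
                self.counts.get(c, 0) for c in ("SR", "hnRNP", "pre-mRNA-binding")
            ),
            "miscellaneous": self.counts.get("miscellaneous", 0),
        }


def load_panel(manifest: str | Path, sequences: str | Path | None = None) -> Panel:
    """Load a panel from a TSV manifest plus an optional sequence FASTA.

    The manifest has columns ``id  name  category  paralogue_group`` (tab
    separated, header row required).  When *sequences* is omitted every
    entry receives the placeholder sequence ``"X"`` — enough for counting
    and summary work, not for homology search.
    """
    df = pd.read_csv(manifest, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    seqs: dict[str, str] = {}
    if sequences is not None:
        for rec in SeqIO.parse(str(sequences), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
    entries: list[PanelEntry] = []
    for row in df.itertuples(index=False):
        if sequences is not None:
            if row.id not in seqs:
                raise ValueError(f"manifest/FASTA mismatch: no sequence for {row.id!r}")
            seq = seqs[row.id]
        else:
            seq = "X"
        entries.append(
            PanelEntry(
                id=row.id,
                name=row.name,
                category=row.category,
                paralogue_group=row.paralogue_group or None,
                sequence=seq,
            )
        )
    return Panel(entries)


def collapse_paralogues(panel: Panel) -> Panel:
    """Replace each paralogue group by its first-listed member.

    The representative keeps every member sequence so a homology hit to any
    member still satisfies the collapsed entry.  Output size is
    ``len(panel) - sum(group size - 1)``.
    """
    taken: set[str] = set()
    out: list[PanelEntry] = []
    groups = panel.groups
    for e in panel.entries:
        if e.paralogue_group is None:
            out.append(e)
            continue
        if e.paralogue_group in taken:
            continue
        taken.add(e.paralogue_group)
        members = tuple(
            (m, panel.get(m).sequence) for m in groups[e.paralogue_group]
        )
        out.append(replace(e, members=members))
    return Panel(out)


def summarize_panel(panel: Panel) -> PanelSummary:
    counts = Counter(e.category for e in panel.entries)
    return PanelSummary(counts=dict(counts), total=len(panel.entries))


def packaged_manifest_path() -> Path:
    """Path of the bundled reference-panel manifest (names and categories only)."""
    return Path(str(resources.files("spliceopanel").joinpath("data/panel_manifest.tsv")))


def load_reference_panel() -> Panel:
    """The bundled human reference panel with placeholder sequences."""
    return load_panel(packaged_manifest_path())
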