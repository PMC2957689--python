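"""Readers and writers for every external file the pipeline touches.

Formats handled here:

* FASTA proteomes (one file per species; species identity comes from the
  run configuration, never from headers).
* 12-column BLAST-style tabular hit files (tab-separated, ``#`` comments
  allowed) — used both for domain hits against a profile database and for
  precomputed pairwise protein similarity.
* The ortholog-group report: one block per group, the group ID on its own
  line followed by one ``species<TAB>protein`` line per member, blocks
  separated by a blank line, groups sorted by ID.
* ``PfamArcMap.txt``: tab-separated map from a domain-based group-ID stem
  to its "/"-joined architecture string.
* The simulator truth table (TSV).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence tagged with the species it belongs to.

    ``protein_id`` must be unique across the whole run (not merely within
    its species); trailing ``*`` stop characters have already been
    stripped by :func:`read_proteomes`.
    """

    protein_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(
                f"protein {self.protein_id!r} ({self.species_id}) has an empty sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TabularHit:
    """One row of a 12-column BLAST-style tabular file.

    Coordinates are 1-based inclusive, exactly as printed by the usual
    profile/protein search tools.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_start {self.q_start} > q_end {self.q_end}"
            )
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative evalue")
        if self.bit_score < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative bit score")


def read_proteomes(
    paths: Sequence[str | Path], species_labels: Sequence[str]
) -> list[ProteinRecord]:
    """Read one FASTA file per species and tag records with species labels.

    Trailing ``*`` stop characters are stripped; every other residue
    character is kept verbatim. Duplicate protein IDs (within a species or
    across species) and empty files are errors.
    """
    if len(paths) != len(species_labels):
        raise ValueError(
            f"{len(paths)} FASTA paths but {len(species_labels)} species labels"
        )
    if len(set(species_labels)) != len(species_labels):
        raise ValueError("species labels must be unique")
    records: list[ProteinRecord] = []
    seen_ids: dict[str, str] = {}
    for path, species in zip(paths, species_labels):
        n_before = len(records)
        for rec in SeqIO.parse(str(path), "fasta"):
            pid = rec.id
            if not pid:
                raise ValueError(f"{path}: record with empty header")
            if pid in seen_ids:
                raise ValueError(
                    f"duplicate protein id {pid!r} (first seen in species "
                    f"{seen_ids[pid]!r}, again in {species!r})"
                )
            seen_ids[pid] = species
            seq = str(rec.seq).strip().rstrip("*")
            records.append(ProteinRecord(protein_id=pid, species_id=species, sequence=seq))
        if len(records) == n_before:
            raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


_TABULAR_COLUMNS = 12


def read_tabular_hits(path: str | Path) -> list[TabularHit]:
    """Parse a 12-column tab-separated hit file; ``#`` comment lines are skipped."""
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _TABULAR_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_TABULAR_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                hits.append(
                    TabularHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


_GROUP_ID_RE = re.compile(r"^(PfamArcNu|NoDomainInfo)(\d+)$")


def _group_sort_key(group_id: str) -> tuple:
    m = _GROUP_ID_RE.match(group_id)
    if m:
        return (m.group(1), int(m.group(2)))
    return (group_id, -1)


def write_ortholog_report(groups, path: str | Path) -> None:
    """Write the ortholog report: blocks of group ID + member lines.

    ``groups`` is an iterable of objects with ``group_id`` and ``members``
    (a set of ``(species_id, protein_id)`` tuples). Groups are sorted by
    ID (prefix, then numeric suffix); members by species then protein.
    """
    ordered = sorted(groups, key=lambda g: _group_sort_key(g.group_id))
    with open(path, "w") as fh:
        for g in ordered:
            if g.group_id is None:
                raise ValueError("group without an assigned ID cannot be reported")
            fh.write(g.group_id + "\n")
            for species, protein in sorted(g.members):
                fh.write(f"{species}\t{protein}\n")
            fh.write("\n")


def read_ortholog_report(path: str | Path) -> list[tuple[str, set[tuple[str, str]]]]:
    """Read the ortholog report back as ``(group_id, member set)`` blocks."""
    blocks: list[tuple[str, set[tuple[str, str]]]] = []
    current_id: str | None = None
    current_members: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                if current_id is not None:
                    blocks.append((current_id, current_members))
                    current_id, current_members = None, set()
                continue
            if "\t" in line:
                if current_id is None:
                    raise ValueError(f"{path}: member line before any group ID: {line!r}")
                species, protein = line.split("\t")
                current_members.add((species, protein))
            else:
                if current_id is not None:
                    blocks.append((current_id, current_members))
                    current_members = set()
                current_id = line.strip()
    if current_id is not None:
        blocks.append((current_id, current_members))
    return blocks


ARCHITECTURE_MAP_FILENAME = "PfamArcMap.txt"


def write_architecture_map(groups, path: str | Path) -> None:
    """Write the architecture map for domain-based homolog groups.

    One line per characterized group: ``PfamArcNu<index><TAB><A/B/C>``.
    The uncharacterized group (no domains) is absent from the map.
    """
    with open(path, "w") as fh:
        for g in sorted(
            (g for g in groups if not g.architecture.is_uncharacterized),
            key=lambda g: g.index,
        ):
            fh.write(f"PfamArcNu{g.index}\t{g.architecture.string}\n")


def read_architecture_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            stem, arch = line.split("\t")
            mapping[stem] = arch
    return mapping


TRUTH_COLUMNS = ["protein_id", "species_id", "family_id", "duplicated", "rearranged"]


def write_truth_table(truth_df: pd.DataFrame, path: str | Path) -> None:
    truth_df.loc[:, TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "species_id": str, "family_id": str})
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: truth table missing columns {missing}")
    return df


def atomic_write_text(text: str, path: str | Path) -> None:
    """Write ``text`` to ``path`` via a temporary file and atomic rename."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
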