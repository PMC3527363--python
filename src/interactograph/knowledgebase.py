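"""On-disk knowledgebase: a documented four-file TSV dialect.

Files (tab-separated, one header row each, LF endings):

``interactions.tsv``
    record_id, gene_a, tax_a, gene_b, tax_b,
    interaction_type {PP|PD|GI|OTHER}, direction {AB|NONE},
    pubmed_ids (comma-joined integers), submitter (empty = curated import),
    status {curated|user}

``gene_info.tsv``
    gene_id, tax_id, symbol, synonyms (pipe-joined), description,
    go_terms (pipe-joined)

``homologene.tsv``
    homologene_id, gene_id, tax_id  (one row per group member)

``history.tsv``
    sequence_no, action {add|revert}, record_id, user, timestamp

Writing is canonical (interactions by record_id, genes by gene_id,
homology rows by (group, tax, gene), history by sequence number) so that
``load`` followed by ``write`` is a byte-identity on canonical files.
"""

from __future__ import annotations

import csv
import logging
import os
from pathlib import Path
from typing import Iterable, Optional

from .errors import IntegrityError, ParseError
from .model import (
    AnnotationStatus,
    ChangeAction,
    ChangeEvent,
    GeneInfo,
    GeneRef,
    HomologyGroup,
    InteractionRecord,
    InteractionType,
    Knowledgebase,
)

logger = logging.getLogger(__name__)

INTERACTIONS_FILE = "interactions.tsv"
GENE_INFO_FILE = "gene_info.tsv"
HOMOLOGENE_FILE = "homologene.tsv"
HISTORY_FILE = "history.tsv"

_INTERACTION_COLS = [
    "record_id", "gene_a", "tax_a", "gene_b", "tax_b",
    "interaction_type", "direction", "pubmed_ids", "submitter", "status",
]
_GENE_COLS = ["gene_id", "tax_id", "symbol", "synonyms", "description", "go_terms"]
_HOMOLOGY_COLS = ["homologene_id", "gene_id", "tax_id"]
_HISTORY_COLS = ["sequence_no", "action", "record_id", "user", "timestamp"]


def _read_rows(path: Path, expected_header: list[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(str(path), 1, "empty file (header row required)")
        if header != expected_header:
            raise ParseError(
                str(path), 1,
                f"bad header: expected {expected_header}, got {header}",
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected_header):
                raise ParseError(
                    str(path), lineno,
                    f"expected {len(expected_header)} columns, got {len(row)}",
                )
            yield lineno, row


def _int_field(path: Path, lineno: int, name: str, raw: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ParseError(str(path), lineno, f"{name} is not an integer: {raw!r}") from None


def _parse_interaction(path: Path, lineno: int, row: list[str]) -> InteractionRecord:
    rid = _int_field(path, lineno, "record_id", row[0])
    ga = _int_field(path, lineno, "gene_a", row[1])
    ta = _int_field(path, lineno, "tax_a", row[2])
    gb = _int_field(path, lineno, "gene_b", row[3])
    tb = _int_field(path, lineno, "tax_b", row[4])
    try:
        itype = InteractionType.from_code(row[5])
    except ValueError as exc:
        raise ParseError(str(path), lineno, str(exc)) from None
    direction = row[6]
    if direction not in ("AB", "NONE"):
        raise ParseError(str(path), lineno, f"direction must be AB or NONE, got {direction!r}")
    pubmed_raw = row[7].strip()
    if not pubmed_raw:
        raise ParseError(str(path), lineno, "pubmed_ids is empty (every interaction needs >=1 PubMed reference)")
    pubmed = tuple(
        _int_field(path, lineno, "pubmed_ids", tok) for tok in pubmed_raw.split(",")
    )
    submitter = row[8] or None
    try:
        status = AnnotationStatus(row[9])
    except ValueError:
        raise ParseError(str(path), lineno, f"status must be curated or user, got {row[9]!r}") from None
    rec = InteractionRecord(
        record_id=rid,
        subject=GeneRef(tax_id=ta, gene_id=ga),
        object=GeneRef(tax_id=tb, gene_id=gb),
        interaction_type=itype,
        directed=(direction == "AB"),
        pubmed_ids=pubmed,
        submitter=submitter,
        annotation_status=status,
    )
    try:
        rec.validate()
    except ValueError as exc:
        raise ParseError(str(path), lineno, str(exc)) from None
    return rec


def load_knowledgebase(
    interactions_path: os.PathLike | str,
    gene_info_path: os.PathLike | str,
    homology_path: os.PathLike | str,
    history_path: os.PathLike | str | None = None,
) -> Knowledgebase:
    """Load and validate the three data tables (plus an optional history
    table).  Malformed rows raise :class:`ParseError` naming the line;
    cross-row violations raise :class:`IntegrityError` listing every
    offending row."""
    interactions_path = Path(interactions_path)
    gene_info_path = Path(gene_info_path)
    homology_path = Path(homology_path)
    for p in (interactions_path, gene_info_path, homology_path):
        if not p.exists():
            raise FileNotFoundError(p)

    kb = Knowledgebase()

    for lineno, row in _read_rows(gene_info_path, _GENE_COLS):
        gid = _int_field(gene_info_path, lineno, "gene_id", row[0])
        tid = _int_field(gene_info_path, lineno, "tax_id", row[1])
        if gid in kb.genes:
            raise IntegrityError(f"{gene_info_path}: duplicate gene_id {gid} (line {lineno})")
        kb.genes[gid] = GeneInfo(
            gene=GeneRef(tax_id=tid, gene_id=gid),
            official_symbol=row[2],
            synonyms=tuple(s for s in row[3].split("|") if s),
            description=row[4],
            go_terms=tuple(t for t in row[5].split("|") if t),
        )

    # official symbol uniqueness within a taxon (case-insensitive)
    seen_symbols: dict[tuple[int, str], int] = {}
    for info in kb.genes.values():
        key = (info.tax_id, info.official_symbol.casefold())
        if key in seen_symbols:
            raise IntegrityError(
                f"official symbol {info.official_symbol!r} duplicated within "
                f"taxon {info.tax_id} (genes {seen_symbols[key]} and {info.gene_id})"
            )
        seen_symbols[key] = info.gene_id

    violations: list[str] = []
    seen_ids: set[int] = set()
    orphans: set[int] = set()
    for lineno, row in _read_rows(interactions_path, _INTERACTION_COLS):
        rec = _parse_interaction(interactions_path, lineno, row)
        if rec.record_id in seen_ids:
            raise IntegrityError(
                f"{interactions_path}: duplicate record_id {rec.record_id} (line {lineno})"
            )
        seen_ids.add(rec.record_id)
        for ref in rec.endpoints:
            info = kb.genes.get(ref.gene_id)
            if info is None:
                orphans.add(ref.gene_id)
            elif info.tax_id != ref.tax_id:
                violations.append(
                    f"line {lineno}: gene {ref.gene_id} carries tax {ref.tax_id} "
                    f"but gene_info records tax {info.tax_id}"
                )
        kb.interactions.append(rec)
    if violations:
        raise IntegrityError(
            f"{interactions_path}: taxon mismatches against gene_info: "
            + "; ".join(violations)
        )
    if orphans:
        logger.warning(
            "%d interacting gene id(s) missing from gene_info (tolerated, "
            "labeled by raw id): %s",
            len(orphans), sorted(orphans)[:10],
        )

    members: dict[int, list[GeneRef]] = {}
    assigned: dict[int, int] = {}
    for lineno, row in _read_rows(homology_path, _HOMOLOGY_COLS):
        hid = _int_field(homology_path, lineno, "homologene_id", row[0])
        gid = _int_field(homology_path, lineno, "gene_id", row[1])
        tid = _int_field(homology_path, lineno, "tax_id", row[2])
        if gid in assigned and assigned[gid] != hid:
            raise IntegrityError(
                f"{homology_path}: gene {gid} assigned to homology groups "
                f"{assigned[gid]} and {hid} (line {lineno})"
            )
        assigned[gid] = hid
        members.setdefault(hid, []).append(GeneRef(tax_id=tid, gene_id=gid))
    for hid, refs in members.items():
        if len(refs) < 2:
            raise IntegrityError(f"{homology_path}: homology group {hid} has <2 members")
        kb.homology_groups[hid] = HomologyGroup(
            homologene_id=hid, members=tuple(sorted(refs))
        )

    if history_path is not None and Path(history_path).exists():
        by_id = {r.record_id: r for r in kb.interactions}
        last_seq = 0
        for lineno, row in _read_rows(Path(history_path), _HISTORY_COLS):
            seq = _int_field(Path(history_path), lineno, "sequence_no", row[0])
            if seq <= last_seq:
                raise IntegrityError(
                    f"{history_path}: sequence_no not strictly increasing at line {lineno}"
                )
            last_seq = seq
            try:
                action = ChangeAction(row[1])
            except ValueError:
                raise ParseError(str(history_path), lineno, f"unknown action {row[1]!r}") from None
            rid = _int_field(Path(history_path), lineno, "record_id", row[2])
            kb.history.append(
                ChangeEvent(
                    sequence_no=seq,
                    action=action,
                    record=by_id.get(rid),
                    user=row[3],
                    timestamp=row[4],
                    record_id_hint=rid,
                )
            )

    kb.reindex()
    return kb


def load_knowledgebase_dir(directory: os.PathLike | str) -> Knowledgebase:
    """Load a knowledgebase from a directory holding the canonical
    file names."""
    d = Path(directory)
    return load_knowledgebase(
        d / INTERACTIONS_FILE,
        d / GENE_INFO_FILE,
        d / HOMOLOGENE_FILE,
        d / HISTORY_FILE,
    )


def _format_interaction(rec: InteractionRecord) -> list[str]:
    return [
        str(rec.record_id),
        str(rec.subject.gene_id), str(rec.subject.tax_id),
        str(rec.object.gene_id), str(rec.object.tax_id),
        rec.interaction_type.value,
        "AB" if rec.directed else "NONE",
        ",".join(str(p) for p in rec.pubmed_ids),
        rec.submitter or "",
        rec.annotation_status.value,
    ]


def write_knowledgebase(kb: Knowledgebase, directory: os.PathLike | str) -> dict[str, Path]:
    """Write the canonical TSVs into ``directory`` and return the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": d / INTERACTIONS_FILE,
        "gene_info": d / GENE_INFO_FILE,
        "homologene": d / HOMOLOGENE_FILE,
        "history": d / HISTORY_FILE,
    }

    def _write(path: Path, header: list[str], rows: Iterable[list[str]]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    _write(
        paths["interactions"], _INTERACTION_COLS,
        (_format_interaction(r) for r in sorted(kb.interactions, key=lambda r: r.record_id)),
    )
    _write(
        paths["gene_info"], _GENE_COLS,
        (
            [
                str(g.gene_id), str(g.tax_id), g.official_symbol,
                "|".join(g.synonyms), g.description, "|".join(g.go_terms),
            ]
            for g in sorted(kb.genes.values(), key=lambda g: g.gene_id)
        ),
    )
    homology_rows = sorted(
        (
            (grp.homologene_id, m.tax_id, m.gene_id)
            for grp in kb.homology_groups.values()
            for m in grp.members
        )
    )
    _write(
        paths["homologene"], _HOMOLOGY_COLS,
        ([str(h), str(g), str(t)] for h, t, g in homology_rows),
    )
    _write(
        paths["history"], _HISTORY_COLS,
        (
            [str(e.sequence_no), e.action.value, str(e.record_id), e.user, e.timestamp]
            for e in sorted(kb.history, key=lambda e: e.sequence_no)
        ),
    )
    return paths


def serialize_state(kb: Knowledgebase) -> str:
    """Canonical text form of the knowledge state (interactions, genes,
    homology) used for state-equality checks; the audit history is an
    append-only log and deliberately excluded."""
    import io

    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    for rec in sorted(kb.interactions, key=lambda r: r.record_id):
        writer.writerow(_format_interaction(rec))
    for g in sorted(kb.genes.values(), key=lambda g: g.gene_id):
        writer.writerow([str(g.gene_id), str(g.tax_id), g.official_symbol,
                         "|".join(g.synonyms), g.description, "|".join(g.go_terms)])
    for grp in sorted(kb.homology_groups.values(), key=lambda g: g.homologene_id):
        writer.writerow([str(grp.homologene_id)] + [f"{m.tax_id}:{m.gene_id}" for m in grp.members])
    return out.getvalue()


def replay_history(
    baseline: Iterable[InteractionRecord],
    history: Iterable[ChangeEvent],
) -> list[InteractionRecord]:
    """Replay the change log on top of a curated baseline: ``add`` events
    append their record, ``revert`` events remove it again.  Replaying a
    knowledgebase's own history over its curated records reproduces its
    interaction table exactly."""
    current: list[InteractionRecord] = list(baseline)
    for event in sorted(history, key=lambda e: e.sequence_no):
        if event.action is ChangeAction.add:
            if event.record is None:
                raise ValueError(
                    f"add event {event.sequence_no} lacks its record; cannot replay"
                )
            current.append(event.record)
        else:
            current = [r for r in current if r.record_id != event.record_id]
    return current
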