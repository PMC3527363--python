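"""Crowdsourced curation: pre-check, commit, revert.

Users pre-submit a proposed interaction; the pre-check validates the
fields, echoes the resolved gene information and PubMed ids back, and
warns when the proposal duplicates an existing record (same gene pair
and type; direction compared only for directed types).  A warning is
advisory — a new citation for a known interaction may be force-committed
as additional documentation.  Every commit is attributed to its
submitter and logged in the append-only history, which supports
reverting the knowledgebase to any earlier state.
"""

from __future__ import annotations

import copy
import datetime
import enum
from dataclasses import dataclass, field
from typing import Optional

from .errors import SubmissionError
from .model import (
    AnnotationStatus,
    ChangeAction,
    ChangeEvent,
    GeneRef,
    InteractionRecord,
    InteractionType,
    Knowledgebase,
)


@dataclass(frozen=True)
class SubmissionProposal:
    subject: GeneRef
    object: GeneRef
    interaction_type: InteractionType
    directed: bool
    pubmed_ids: tuple[int, ...]
    submitter: str

    def as_record(self, record_id: int) -> InteractionRecord:
        return InteractionRecord(
            record_id=record_id,
            subject=self.subject,
            object=self.object,
            interaction_type=self.interaction_type,
            directed=self.directed,
            pubmed_ids=self.pubmed_ids,
            submitter=self.submitter,
            annotation_status=AnnotationStatus.user_submitted,
        )


class VerdictStatus(enum.Enum):
    green_light = "green_light"
    redundant_warning = "redundant_warning"
    invalid = "invalid"


@dataclass
class SubmissionVerdict:
    status: VerdictStatus
    matches: list[int] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


def _field_errors(proposal: SubmissionProposal, registry: Optional[set[str]]) -> list[str]:
    errors = []
    if not proposal.pubmed_ids:
        errors.append("at least one PubMed id is required")
    elif any(p <= 0 for p in proposal.pubmed_ids):
        errors.append("PubMed ids must be positive integers")
    expect_directed = proposal.interaction_type is InteractionType.protein_dna
    if proposal.directed != expect_directed:
        errors.append(
            f"direction flag inconsistent with type {proposal.interaction_type.value}"
        )
    if not proposal.submitter:
        errors.append("a submitter name is required")
    elif registry is not None and proposal.submitter not in registry:
        errors.append(f"submitter {proposal.submitter!r} is not a registered user")
    return errors


def _redundant_with(proposal: SubmissionProposal, kb: Knowledgebase) -> list[int]:
    """Existing records documenting the same relation: same unordered
    gene pair and type (ordered pair for directed types).  PubMed ids
    are deliberately ignored."""
    if proposal.directed:
        key = (proposal.subject, proposal.object, proposal.interaction_type)
    else:
        a, b = sorted((proposal.subject, proposal.object))
        key = (a, b, proposal.interaction_type)
    return sorted(r.record_id for r in kb.interactions if r.pair_key() == key)


def precheck(
    proposal: SubmissionProposal,
    kb: Knowledgebase,
    registry: Optional[set[str]] = None,
) -> SubmissionVerdict:
    """Validate a proposal and check it for redundancy.  Total and
    read-only: invalid proposals yield status=invalid, never an
    exception, and the knowledgebase is untouched."""
    errors = _field_errors(proposal, registry)
    if errors:
        return SubmissionVerdict(VerdictStatus.invalid, messages=errors)

    messages = [
        f"subject: {kb.label_of(proposal.subject)} "
        f"(gene {proposal.subject.gene_id}, taxon {proposal.subject.tax_id})",
        f"object: {kb.label_of(proposal.object)} "
        f"(gene {proposal.object.gene_id}, taxon {proposal.object.tax_id})",
        "PubMed ids: " + ", ".join(str(p) for p in proposal.pubmed_ids),
    ]
    matches = _redundant_with(proposal, kb)
    if matches:
        messages.append(
            "potential redundancy with existing record(s): "
            + ", ".join(str(m) for m in matches)
        )
        return SubmissionVerdict(VerdictStatus.redundant_warning, matches, messages)
    messages.append("no matching record found: green light")
    return SubmissionVerdict(VerdictStatus.green_light, messages=messages)


def commit(
    proposal: SubmissionProposal,
    kb: Knowledgebase,
    registry: Optional[set[str]] = None,
    force: bool = False,
    timestamp: Optional[str] = None,
) -> int:
    """Append the proposal as a user-submitted record and log the change.

    Redundant proposals are rejected unless ``force`` is given (the
    warning is advisory).  Returns the new record id.
    """
    verdict = precheck(proposal, kb, registry)
    if verdict.status is VerdictStatus.invalid:
        raise SubmissionError(
            "invalid proposal: " + "; ".join(verdict.messages), verdict
        )
    if verdict.status is VerdictStatus.redundant_warning and not force:
        raise SubmissionError(
            "proposal is redundant with record(s) "
            + ", ".join(str(m) for m in verdict.matches)
            + " (use force to commit as additional documentation)",
            verdict,
        )
    record = proposal.as_record(kb.next_record_id())
    kb.interactions.append(record)
    kb.history.append(
        ChangeEvent(
            sequence_no=kb.next_sequence_no(),
            action=ChangeAction.add,
            record=record,
            user=proposal.submitter,
            timestamp=timestamp
            or datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
        )
    )
    return record.record_id


def revert_to(
    kb: Knowledgebase,
    sequence_no: int,
    user: str = "system",
    timestamp: Optional[str] = None,
) -> Knowledgebase:
    """Return a knowledgebase whose state matches history position
    ``sequence_no`` (0 = curated baseline).

    User-submitted records added by events after the target are removed;
    the curated baseline is untouched.  History stays append-only: one
    compensating ``revert`` event is logged per removed record.
    """
    known = {e.sequence_no for e in kb.history}
    if sequence_no != 0 and sequence_no not in known:
        raise SubmissionError(f"unknown history sequence number {sequence_no}")

    new_kb = copy.deepcopy(kb)
    ts = timestamp or datetime.datetime.now(datetime.timezone.utc).isoformat(
        timespec="seconds"
    )
    # records currently present that were added after the target
    to_remove = [
        e
        for e in sorted(kb.history, key=lambda e: e.sequence_no)
        if e.sequence_no > sequence_no
        and e.action is ChangeAction.add
        and any(r.record_id == e.record_id for r in new_kb.interactions)
    ]
    for event in to_remove:
        new_kb.interactions = [
            r for r in new_kb.interactions if r.record_id != event.record_id
        ]
        new_kb.history.append(
            ChangeEvent(
                sequence_no=new_kb.next_sequence_no(),
                action=ChangeAction.revert,
                record=event.record,
                user=user,
                timestamp=ts,
            )
        )
    return new_kb
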