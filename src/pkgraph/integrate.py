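"""Integration of two author-name-disambiguation results.

The *primary* clustering is the high-precision source whose labels are
authoritative but whose coverage stops early in time; the *secondary*
clustering covers everything but is noisier.  Integration keeps every
primary label and uses the secondary clusters only to extend coverage:

1. every instance labeled in the primary keeps its primary label;
2. a secondary cluster none of whose members carry a primary label gets
   one freshly allocated label (continuing the primary label space) for
   all of its members;
3. a secondary cluster containing primary-labeled members propagates a
   primary label to its unlabeled members.

When a secondary cluster spans two or more distinct primary labels (a
lumping disagreement between the sources) the labeled members keep their
own labels and unlabeled members take the majority primary label within
the cluster, ties to the smallest label; the event is recorded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .models import Clustering, ValidationError

logger = logging.getLogger(__name__)

#: Provenance values for integrated assignments.
PRIMARY = "primary"
SECONDARY_NEW = "secondary-new"
SECONDARY_PROPAGATED = "secondary-propagated"
UNASSIGNED = "unassigned"


@dataclass
class IdAllocator:
    """Allocates fresh labels strictly above every primary label."""

    next_id: int

    @classmethod
    def continuing(cls, primary: Clustering) -> "IdAllocator":
        return cls(next_id=primary.max_label() + 1)

    def allocate(self) -> int:
        label = self.next_id
        self.next_id += 1
        return label


@dataclass
class ConflictRecord:
    """A secondary cluster whose members carry >= 2 distinct primary labels."""

    secondary_label: int
    primary_labels: frozenset[int]
    members: tuple[int, ...]


@dataclass
class IntegratedAssignment:
    """The merged assignment plus per-instance provenance and the list of
    cross-source conflicts encountered."""

    assignments: dict[int, int]
    provenance: dict[int, str]
    conflicts: list[ConflictRecord] = field(default_factory=list)

    def clustering(self) -> Clustering:
        return Clustering(self.assignments)

    def label_of(self, instance_id: int) -> int:
        return self.assignments.get(instance_id, 0)


def detect_conflicts(primary: Clustering, secondary: Clustering) -> list[ConflictRecord]:
    """List every secondary cluster spanning >= 2 distinct primary labels.

    Empty when the two sources are consistent.
    """
    out = []
    for sec_label, members in sorted(secondary.clusters().items()):
        labels = frozenset(
            primary.label_of(m) for m in members if primary.label_of(m) > 0
        )
        if len(labels) >= 2:
            out.append(ConflictRecord(sec_label, labels, tuple(members)))
    return out


def integrate(primary: Clustering, secondary: Clustering) -> IntegratedAssignment:
    """Merge the two clusterings; see the module docstring for the rules.

    Deterministic: secondary clusters are processed in ascending order of
    their smallest member instance ID, so fresh labels do not depend on
    input iteration order.  Instances known to neither source are reported
    with label 0 / provenance ``unassigned``.
    """
    assignments: dict[int, int] = {}
    provenance: dict[int, str] = {}
    conflicts: list[ConflictRecord] = []

    # Step 1: primary labels are authoritative.
    for inst, label in primary.assignments.items():
        assignments[inst] = label
        provenance[inst] = PRIMARY

    allocator = IdAllocator.continuing(primary)
    sec_clusters = sorted(secondary.clusters().items(), key=lambda kv: min(kv[1]))

    for sec_label, members in sec_clusters:
        primary_labels = [primary.label_of(m) for m in members]
        labeled = [lab for lab in primary_labels if lab > 0]
        unlabeled = [m for m, lab in zip(members, primary_labels) if lab == 0]

        if not labeled:
            # Step 2: an author entirely missing from the primary source.
            fresh = allocator.allocate()
            for m in members:
                assignments[m] = fresh
                provenance[m] = SECONDARY_NEW
            continue

        # Step 3: propagate a primary label to the uncovered members.
        distinct = frozenset(labeled)
        if len(distinct) >= 2:
            conflict = ConflictRecord(sec_label, distinct, tuple(members))
            conflicts.append(conflict)
            logger.warning(
                "secondary cluster %d spans primary labels %s",
                sec_label, sorted(distinct))
        counts = Counter(labeled)
        top = max(counts.values())
        propagated = min(lab for lab, c in counts.items() if c == top)
        for m in unlabeled:
            assignments[m] = propagated
            provenance[m] = SECONDARY_PROPAGATED

    # Instances in neither labeling stay unassigned but are reported.
    for inst in set(primary.assignments) | set(secondary.assignments):
        if inst not in assignments:
            provenance[inst] = UNASSIGNED

    return IntegratedAssignment(assignments=assignments, provenance=provenance,
                                conflicts=conflicts)


def read_clustering_csv(path) -> Clustering:
    """Read a 2-column CSV (instance_id, label) into a Clustering.

    An instance appearing twice with different labels is an input error.
    """
    import csv

    seen: dict[int, int] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"{path}: empty clustering file")
        rows = [header] if header and header[0].lstrip("-").isdigit() else []
        rows.extend(reader)
    for row in rows:
        if not row:
            continue
        inst, label = int(row[0]), int(row[1])
        if inst in seen and seen[inst] != label:
            raise ValidationError(
                f"{path}: instance {inst} labeled both {seen[inst]} and {label}")
        seen[inst] = label
    return Clustering(seen)


def write_clustering_csv(clustering: Clustering, path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["instance_id", "label"])
        for inst in sorted(clustering.assignments):
            writer.writerow([inst, clustering.assignments[inst]])
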