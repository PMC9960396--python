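"""Marker-gene species delineation.

Species-like phage populations are delineated by clustering marker-gene
(DNA polymerase amplicon) nucleotide sequences at an identity threshold
benchmarked against whole-genome average nucleotide identity (ANI): isolate
genomes show a gap between intra-population (marker identity >99%, ANI >97%)
and inter-population (<90%, <88%) comparisons, and a 98% marker threshold
falls inside that gap.

Identity here is global end-gap-free alignment identity: matches divided by
aligned columns after terminal indel columns are trimmed. Ambiguity code N
always counts as a mismatch, including against another N.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ClusterAssignment:
    centroid_id: str
    member_ids: list[str]
    threshold: float


@dataclass(frozen=True)
class AniBenchmarkPair:
    """One isolate-genome pair: marker-gene identity vs. core-gene ANI (%)."""

    marker_identity: float
    core_ani: float

    def __post_init__(self) -> None:
        for v in (self.marker_identity, self.core_ani):
            if not (0.0 <= v <= 100.0):
                raise ValueError("percent identities must be in [0, 100]")


@dataclass
class GapReport:
    """Marker-identity gap between intra- and inter-population pairs."""

    min_intra: float | None
    max_inter: float | None
    gap: tuple[float, float] | None  # (max_inter, min_intra) when a gap exists
    threshold_percent: float | None = None
    threshold_inside_gap: bool | None = None
    gap_defined: bool = True


def _mask_sequence(seq: str, mask_intervals) -> str:
    """Remove masked [start, end) intervals (e.g. a lineage-specific insertion)."""
    if not mask_intervals:
        return seq
    keep = []
    last = 0
    for start, end in sorted(mask_intervals):
        keep.append(seq[last:start])
        last = end
    keep.append(seq[last:])
    return "".join(keep)


def pairwise_identity(a: SequenceRecord, b: SequenceRecord, mask_intervals=None) -> float:
    """Percent identity of two marker sequences under global alignment.

    Matches / aligned columns x 100 after trimming terminal indels from the
    global alignment; symmetric; in [0, 100].  A pair with no alignable
    overlap (all columns are terminal gaps) returns 0.0 with a warning.
    """
    # canonical argument order: co-optimal alignment paths differ between
    # orderings, so fix one to guarantee exact symmetry
    if (b.length, b.seq) < (a.length, a.seq):
        a, b = b, a
    sa = _mask_sequence(a.seq.upper(), mask_intervals)
    sb = _mask_sequence(b.seq.upper(), mask_intervals)
    # distinct sentinels force N to mismatch everything, including another N
    sa = sa.replace("N", "!")
    sb = sb.replace("N", "?")
    res = edlib.align(sa, sb, mode="NW", task="path")
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"])]
    # trim terminal indel runs: end gaps are not aligned columns
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    columns = sum(n for n, _ in ops)
    if columns == 0:
        warnings.warn(f"no alignable overlap between {a.id!r} and {b.id!r}")
        return 0.0
    matches = sum(n for n, op in ops if op == "=")
    return 100.0 * matches / columns


def dereplicate(records: list[SequenceRecord]) -> dict[str, list[str]]:
    """Collapse exact duplicate sequences; representative = first id in sorted order."""
    by_seq: dict[str, list[str]] = {}
    for r in records:
        by_seq.setdefault(r.seq.upper(), []).append(r.id)
    return {min(ids): sorted(ids) for ids in by_seq.values()}


def dereplicate_and_cluster(
    records: list[SequenceRecord], threshold: float = 0.98, mask_intervals=None
) -> list[ClusterAssignment]:
    """Greedy centroid clustering at a fractional identity threshold.

    Exact duplicates are collapsed first. Unique sequences are processed in
    decreasing length order (ties broken lexicographically by id); each joins
    the first existing centroid it matches at >= threshold, else founds a new
    cluster. Deterministic by construction.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if not records:
        return []
    if len({r.id for r in records}) != len(records):
        raise ValueError("sequence ids must be unique")
    dedup = dereplicate(records)
    rec_by_id = {r.id: r for r in records}
    uniques = sorted(dedup, key=lambda i: (-rec_by_id[i].length, i))
    clusters: list[ClusterAssignment] = []
    for sid in uniques:
        rec = rec_by_id[sid]
        placed = False
        for cl in clusters:
            ident = pairwise_identity(rec_by_id[cl.centroid_id], rec, mask_intervals)
            if ident >= threshold * 100.0:
                cl.member_ids.extend(dedup[sid])
                placed = True
                break
        if not placed:
            clusters.append(ClusterAssignment(sid, list(dedup[sid]), threshold))
    return clusters


def benchmark_threshold(
    pairs: list[AniBenchmarkPair], candidate_threshold: float | None = None, ani_cut: float = 95.0
) -> GapReport:
    """Locate the marker-identity gap separating intra- from inter-population pairs.

    Pairs with core ANI >= ``ani_cut`` are treated as same-population. When
    the minimum intra-population marker identity exceeds the maximum
    inter-population identity, the open interval between them is the gap and
    a candidate clustering threshold (percent) can be validated against it.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    intra = [p.marker_identity for p in pairs if p.core_ani >= ani_cut]
    inter = [p.marker_identity for p in pairs if p.core_ani < ani_cut]
    if not intra or not inter:
        warnings.warn("all pairs fall in one population class; gap undefined")
        return GapReport(
            min_intra=min(intra) if intra else None,
            max_inter=max(inter) if inter else None,
            gap=None,
            threshold_percent=candidate_threshold,
            threshold_inside_gap=None,
            gap_defined=False,
        )
    min_intra, max_inter = min(intra), max(inter)
    if min_intra > max_inter:
        gap = (max_inter, min_intra)
        inside = None
        if candidate_threshold is not None:
            inside = max_inter < candidate_threshold < min_intra
        return GapReport(min_intra, max_inter, gap, candidate_threshold, inside, True)
    warnings.warn("intra- and inter-population identities overlap; gap undefined")
    return GapReport(min_intra, max_inter, None, candidate_threshold, False, False)


def clusters_to_table(clusters: list[ClusterAssignment], records: list[SequenceRecord]):
    """Long-format cluster table: centroid_id, member_id, identity (percent)."""
    import pandas as pd

    rec_by_id = {r.id: r for r in records}
    rows = []
    for cl in clusters:
        for mid in cl.member_ids:
            ident = (
                100.0
                if mid == cl.centroid_id
                else pairwise_identity(rec_by_id[cl.centroid_id], rec_by_id[mid])
            )
            rows.append({"centroid_id": cl.centroid_id, "member_id": mid, "identity": ident})
    return pd.DataFrame(rows)
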