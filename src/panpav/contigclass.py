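"""Non-reference ("novel") sequence construction from contig-vs-reference alignments.

The map-to-pan strategy keeps, from each accession's assembly, the sequence that
cannot be explained by the reference genome: whole contigs with no reliable
reference alignment, and long internal stretches of partially aligned contigs.
After redundancy removal and contamination screening, the surviving sequences
are appended to the reference to form the pan-genome.

Rules implemented here:

* contigs shorter than ``min_contig_len`` (default 500 bp) are discarded;
* an alignment is *reliable* if its identity is strictly greater than
  ``min_identity`` (default 90%) and its contig-side length is at least
  ``min_aln_len`` (default 300 bp);
* a contig with no reliable alignment is *fully unaligned*; a contig whose
  reliable alignments leave a continuous unaligned region of at least
  ``min_unaligned`` bp (default 500) is *partially unaligned* and contributes
  those regions; anything else is *aligned* and contributes nothing;
* extracted sequences are de-duplicated by greedy clustering at
  ``cluster_identity`` (default 90%), identity estimated by canonical k-mer
  containment;
* sequences with a taxonomy label outside the allowed lineages (default
  Eukaryota / Viridiplantae) are dropped; unlabelled sequences are kept.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._intervals import complement, merge_intervals

__all__ = [
    "AlignmentRecord",
    "ContigClassification",
    "Thresholds",
    "filter_short_contigs",
    "filter_reliable_alignments",
    "classify_contig",
    "classify_contigs",
    "extract_novel_sequences",
    "kmer_set",
    "kmer_identity",
    "remove_redundancy",
    "screen_against_reference",
    "filter_taxonomy",
    "build_pangenome",
    "build_novel_set",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One contig-vs-reference alignment (nucmer ``show-coords``-style).

    Contig coordinates are 0-based half-open and always ascend; reverse-strand
    alignments must be normalized by the reader before construction.
    """

    contig_id: str
    contig_start: int
    contig_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    identity: float  # percent, [0, 100]

    def __post_init__(self) -> None:
        if self.contig_end <= self.contig_start:
            raise ValueError(
                f"malformed alignment for contig {self.contig_id!r}: "
                f"contig_end ({self.contig_end}) <= contig_start ({self.contig_start})"
            )
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(
                f"identity {self.identity} out of [0, 100] for contig {self.contig_id!r}"
            )

    @property
    def aln_len(self) -> int:
        return self.contig_end - self.contig_start


@dataclass(frozen=True)
class ContigClassification:
    contig_id: str
    status: str  # fully_unaligned | partially_unaligned | aligned
    unaligned_segments: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class Thresholds:
    """Filtering thresholds for novel-sequence construction.

    ``min_identity`` is a strict lower bound ("higher than 90%"); the length
    thresholds are inclusive minimum lengths.
    """

    min_identity: float = 90.0
    min_aln_len: int = 300
    min_unaligned: int = 500
    min_contig_len: int = 500
    cluster_identity: float = 90.0
    kmer_size: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100 and 0 < self.cluster_identity <= 100):
            raise ValueError("identity thresholds must lie in (0, 100]")
        if min(self.min_aln_len, self.min_unaligned, self.min_contig_len, self.kmer_size) <= 0:
            raise ValueError("length thresholds must be positive")


def filter_short_contigs(
    contigs: Mapping[str, str], min_contig_len: int = 500
) -> dict[str, str]:
    """Drop contigs shorter than ``min_contig_len`` (a contig of exactly that length is kept)."""
    return {cid: seq for cid, seq in contigs.items() if len(seq) >= min_contig_len}


def filter_reliable_alignments(
    records: Iterable[AlignmentRecord], thresholds: Thresholds = Thresholds()
) -> list[AlignmentRecord]:
    """Keep records with identity strictly above ``min_identity`` and length >= ``min_aln_len``."""
    return [
        r
        for r in records
        if r.identity > thresholds.min_identity and r.aln_len >= thresholds.min_aln_len
    ]


def classify_contig(
    contig_id: str,
    contig_len: int,
    reliable_records: Sequence[AlignmentRecord],
    thresholds: Thresholds = Thresholds(),
) -> ContigClassification:
    """Classify one contig from its reliable alignments.

    No reliable alignment -> ``fully_unaligned``. Otherwise the complement of
    the union of aligned intervals within ``[0, contig_len)`` is computed and
    segments of at least ``min_unaligned`` bp are kept: at least one kept
    segment -> ``partially_unaligned``, none -> ``aligned``.
    """
    for r in reliable_records:
        if r.contig_id != contig_id:
            raise ValueError(f"record for {r.contig_id!r} passed to contig {contig_id!r}")
        if r.contig_end > contig_len:
            raise ValueError(
                f"alignment [{r.contig_start}, {r.contig_end}) exceeds length "
                f"{contig_len} of contig {contig_id!r}"
            )
    if not reliable_records:
        return ContigClassification(contig_id, "fully_unaligned")
    aligned = merge_intervals((r.contig_start, r.contig_end) for r in reliable_records)
    segments = tuple(
        (s, e) for s, e in complement(aligned, 0, contig_len) if e - s >= thresholds.min_unaligned
    )
    if segments:
        return ContigClassification(contig_id, "partially_unaligned", segments)
    return ContigClassification(contig_id, "aligned")


def classify_contigs(
    contigs: Mapping[str, str],
    records: Iterable[AlignmentRecord],
    thresholds: Thresholds = Thresholds(),
) -> dict[str, ContigClassification]:
    """Filter alignments for reliability and classify every contig."""
    reliable = filter_reliable_alignments(records, thresholds)
    by_contig: dict[str, list[AlignmentRecord]] = {cid: [] for cid in contigs}
    for r in reliable:
        if r.contig_id in by_contig:
            by_contig[r.contig_id].append(r)
    return {
        cid: classify_contig(cid, len(seq), by_contig[cid], thresholds)
        for cid, seq in contigs.items()
    }


_SEGMENT_ID = re.compile(r"^(?P<contig>.+):(?P<start>\d+)-(?P<end>\d+)$")


def extract_novel_sequences(
    contigs: Mapping[str, str],
    classifications: Mapping[str, ContigClassification],
) -> dict[str, str]:
    """Collect novel sequence: whole fully-unaligned contigs, and the unaligned
    segments of partially-unaligned contigs under ids ``<contig>:<start>-<end>``.
    """
    out: dict[str, str] = {}
    for cid, cls in classifications.items():
        seq = contigs[cid]
        if cls.status == "fully_unaligned":
            out[cid] = seq
        elif cls.status == "partially_unaligned":
            for s, e in cls.unaligned_segments:
                if not (0 <= s < e <= len(seq)):
                    raise ValueError(f"segment [{s}, {e}) outside contig {cid!r}")
                out[f"{cid}:{s}-{e}"] = seq[s:e]
    return out


def parse_segment_id(seq_id: str) -> tuple[str, int, int] | None:
    """Invert the ``<contig>:<start>-<end>`` provenance id; None for whole contigs."""
    m = _SEGMENT_ID.match(seq_id)
    if m is None:
        return None
    return m.group("contig"), int(m.group("start")), int(m.group("end"))


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_set(seq: str, k: int = 15) -> frozenset[str]:
    """Canonical k-mer set (min of k-mer and its reverse complement), uppercase."""
    seq = seq.upper()
    rc = _revcomp(seq)
    n = len(seq)
    return frozenset(
        min(seq[i : i + k], rc[n - i - k : n - i]) for i in range(n - k + 1)
    )


def kmer_identity(query: str, target: str, k: int = 15) -> tuple[float, float]:
    """Containment of the shorter sequence's canonical k-mers in the longer's,
    and the per-base identity it implies.

    Under independent substitutions at rate ``p`` the expected containment is
    ``(1 - p)^k``, so identity is estimated as ``containment ** (1/k)`` (0 when
    no k-mer is shared). Returns ``(containment, identity_percent)``.
    """
    short, long_ = (query, target) if len(query) <= len(target) else (target, query)
    if len(short) < k:
        return 0.0, 0.0
    ks = kmer_set(short, k)
    kl = kmer_set(long_, k)
    containment = len(ks & kl) / len(ks)
    identity = 100.0 * containment ** (1.0 / k) if containment > 0 else 0.0
    return containment, identity


def remove_redundancy(
    sequences: Mapping[str, str],
    cluster_identity: float = 90.0,
    k: int = 15,
    min_containment_cov: float = 0.8,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy length-sorted clustering of novel sequences.

    Sequences are visited longest first (ties broken by id); each joins the
    first cluster whose representative shares at least
    ``min_containment_cov * (cluster_identity/100)**k`` of its canonical
    k-mers (containment measured on the shorter sequence, so a sub-sequence of
    a representative at the required identity over >=80% of its length joins).
    Returns ``(representatives, member -> representative map)``; representatives
    map to themselves.
    """
    threshold = min_containment_cov * (cluster_identity / 100.0) ** k
    order = sorted(sequences, key=lambda cid: (-len(sequences[cid]), cid))
    reps: dict[str, str] = {}
    rep_kmers: dict[str, frozenset[str]] = {}
    assignment: dict[str, str] = {}
    for cid in order:
        seq = sequences[cid]
        kms = kmer_set(seq, k) if len(seq) >= k else frozenset()
        placed = False
        for rep_id in reps:
            shared = kms & rep_kmers[rep_id]
            if kms and len(shared) / len(kms) >= threshold:
                assignment[cid] = rep_id
                placed = True
                break
        if not placed:
            reps[cid] = seq
            rep_kmers[cid] = kms
            assignment[cid] = cid
    return reps, assignment


def screen_against_reference(
    sequences: Mapping[str, str],
    reference: Mapping[str, str],
    cluster_identity: float = 90.0,
    k: int = 15,
    min_containment_cov: float = 0.8,
) -> dict[str, str]:
    """Final re-screen: drop candidate novel sequences still contained in the
    reference at the clustering identity (k-mer containment criterion)."""
    threshold = min_containment_cov * (cluster_identity / 100.0) ** k
    ref_kmers: set[str] = set()
    for seq in reference.values():
        ref_kmers.update(kmer_set(seq, k))
    kept: dict[str, str] = {}
    for cid, seq in sequences.items():
        kms = kmer_set(seq, k) if len(seq) >= k else frozenset()
        if kms and len(kms & ref_kmers) / len(kms) >= threshold:
            continue
        kept[cid] = seq
    return kept


DEFAULT_ALLOWED_LINEAGES = frozenset({"Eukaryota", "Viridiplantae"})


def filter_taxonomy(
    sequences: Mapping[str, str],
    labels: Mapping[str, str],
    allowed: frozenset[str] = DEFAULT_ALLOWED_LINEAGES,
) -> dict[str, str]:
    """Drop sequences whose taxonomy label falls outside the allowed lineages.

    Sequences absent from the label table, or labelled ``unlabelled``, are kept
    (no evidence of contamination).
    """
    out: dict[str, str] = {}
    for cid, seq in sequences.items():
        label = labels.get(cid, "unlabelled")
        if label != "unlabelled" and label not in allowed:
            continue
        out[cid] = seq
    return out


def build_pangenome(
    reference: Mapping[str, str], novel: Mapping[str, str]
) -> tuple[dict[str, str], "pd.DataFrame"]:
    """Merge reference and novel sequences; returns the pan-genome and a
    provenance table flagging each sequence ``reference`` or ``additional``."""
    import pandas as pd

    collision = set(reference) & set(novel)
    if collision:
        raise ValueError(f"sequence id collision between reference and novel set: {sorted(collision)[:5]}")
    pan = {**reference, **novel}
    provenance = pd.DataFrame(
        {
            "seq_id": list(reference) + list(novel),
            "source": ["reference"] * len(reference) + ["additional"] * len(novel),
            "length": [len(reference[c]) for c in reference] + [len(novel[c]) for c in novel],
        }
    )
    return pan, provenance


def build_novel_set(
    contigs: Mapping[str, str],
    records: Iterable[AlignmentRecord],
    taxonomy: Mapping[str, str] | None = None,
    reference: Mapping[str, str] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> tuple[dict[str, str], dict[str, ContigClassification], dict[str, str]]:
    """Full novel-sequence pipeline: length filter, classification, extraction,
    redundancy removal, optional reference re-screen and taxonomy filter.

    Taxonomy labels are looked up by originating contig id, so segment ids
    inherit their contig's label. Returns
    ``(novel sequences, classifications, cluster assignment)``.
    """
    kept = filter_short_contigs(contigs, thresholds.min_contig_len)
    classifications = classify_contigs(kept, records, thresholds)
    extracted = extract_novel_sequences(kept, classifications)
    reps, assignment = remove_redundancy(
        extracted, thresholds.cluster_identity, thresholds.kmer_size
    )
    if reference is not None:
        reps = screen_against_reference(
            reps, reference, thresholds.cluster_identity, thresholds.kmer_size
        )
    if taxonomy is not None:
        seg_labels = {}
        for seq_id in reps:
            parsed = parse_segment_id(seq_id)
            origin = parsed[0] if parsed and parsed[0] in contigs else seq_id
            seg_labels[seq_id] = taxonomy.get(origin, "unlabelled")
        reps = filter_taxonomy(reps, seg_labels)
    return reps, classifications, assignment
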