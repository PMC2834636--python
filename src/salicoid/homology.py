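"""Similarity search of marker fragments and ortholog/paralog classification.

The search is a self-contained screen-and-extend local alignment over a
closed set of located reference sequences (FASTA headers
``>chrom:start-end``): a banded infix edit-distance screen (edlib) on both
strands nominates candidate loci, which are then scored by local alignment
(match +2, mismatch -3, gap open -5, gap extend -2, the classic BLASTN
scheme).  Hit significance is a raw-score threshold; there is no E-value
model, since the reference set is closed and desk-sized.  A k-mer index
(default k = 11) is kept for exact-word lookups.

Classification follows the best-hit-plus-map-concordance rule used to sort
markers after a whole-genome duplication: a marker whose best hit overlaps
its expected anchor is the expected ortholog (paralog 1); a best hit at the
anchor's own second-best locus (paralog 2) is accepted as the ortholog of
paralog 2 when the marker's linkage group is a synteny partner of paralog
2's chromosome, and flagged as a discordant anomaly otherwise; anything else
maps to some other genomic region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from Bio import Align
from Bio.Seq import Seq

ORTHOLOG_EXPECTED = "ortholog_expected"
ORTHOLOG_OF_PARALOG2 = "ortholog_of_paralog2"
DISCORDANT_ANOMALY = "discordant_anomaly"
OTHER_REGION = "other_region"

DEFAULT_MIN_SCORE = 40.0
DEFAULT_K = 11


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class Anchor:
    """A located interval, 1-based inclusive.

    ``start``/``end`` may be None for a chromosome-only anchor (published
    tables occasionally give only the chromosome); such an anchor overlaps
    any interval on the same chromosome.
    """

    chrom: str
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self):
        if self.start is not None and self.end is not None \
                and self.start > self.end:
            raise InputError(f"anchor start > end on {self.chrom}")

    def overlaps(self, other: "Anchor") -> bool:
        """>= 1 bp shared on 1-based inclusive intervals; symmetric."""
        if self.chrom != other.chrom:
            return False
        if self.start is None or other.start is None:
            return True
        return max(self.start, other.start) <= min(self.end, other.end)

    @property
    def midpoint(self) -> Optional[float]:
        if self.start is None:
            return None
        return (self.start + self.end) / 2

    def __str__(self) -> str:
        if self.start is None:
            return self.chrom
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class RefSeq:
    """A reference sequence with its genomic location."""

    chrom: str
    start: int
    end: int
    seq: str

    @property
    def anchor(self) -> Anchor:
        return Anchor(self.chrom, self.start, self.end)


@dataclass
class HomologyHit:
    target: Anchor
    score: float
    identity: Optional[float]
    rank: int = 0
    strand: int = 1


@dataclass
class MarkerRecord:
    name: str
    fragment: str
    expected_anchor: Anchor
    linkage_group: Optional[str] = None
    cm: Optional[float] = None


@dataclass
class OrthologyCall:
    marker: str
    category: str
    paralog1: Anchor
    paralog2: Optional[Anchor]
    best_hit: Optional[Anchor]
    evidence: dict = field(default_factory=dict)


def _scoring_aligner(match=2, mismatch=-3, gap_open=-5, gap_extend=-2,
                     mode="local") -> Align.PairwiseAligner:
    # match +2 / mismatch -3 keeps the expected per-column score positive
    # down to ~60% identity, the regime of WGD paralogs near saturation;
    # a +1/-2 scheme drifts negative below ~75% identity and cannot extend
    # through such pairs
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # BLAST-style affine: first gap residue costs open + extend
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_stats(alignment) -> Tuple[float, int, int, int]:
    """(identity, columns, target begin, target end) of a local alignment."""
    tblocks, qblocks = alignment.aligned
    target = alignment.target
    query = alignment.query
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        columns += te - ts
        matches += sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
    # count gap columns between blocks
    for i in range(1, len(tblocks)):
        columns += (tblocks[i][0] - tblocks[i - 1][1]) + \
                   (qblocks[i][0] - qblocks[i - 1][1])
    begin = int(tblocks[0][0])
    end = int(tblocks[-1][1])
    identity = matches / columns if columns else 0.0
    return identity, columns, begin, end


class ReferenceIndex:
    """k-mer index over a set of located reference sequences."""

    def __init__(self, refs: Sequence[RefSeq], k: int = DEFAULT_K):
        self.refs = list(refs)
        self.k = k
        index: Dict[str, List[int]] = {}
        for i, ref in enumerate(self.refs):
            seq = ref.seq.upper()
            for kmer in {seq[j:j + k] for j in range(len(seq) - k + 1)}:
                index.setdefault(kmer, []).append(i)
        self._index = index

    def candidates(self, fragment: str) -> Set[int]:
        return set(self.candidate_counts(fragment))

    def candidate_counts(self, fragment: str) -> Dict[int, int]:
        """ref index -> number of distinct shared k-mers with ``fragment``."""
        frag = fragment.upper()
        counts: Dict[int, int] = {}
        for kmer in {frag[j:j + self.k]
                     for j in range(len(frag) - self.k + 1)}:
            for i in self._index.get(kmer, ()):
                counts[i] = counts.get(i, 0) + 1
        return counts


def _chrom_sort_key(chrom: str):
    return (len(chrom), chrom)


#: candidate screen: keep loci whose best infix edit distance is at most
#: this fraction of the fragment length.  Unrelated random DNA sits near
#: 0.49; WGD paralogs at the saturating end of the method's working range
#: (K ~ 0.4, ~30% mismatch) sit below ~0.38.
DEFAULT_SCREEN_MAX_FRAC = 0.42


def search_hits(fragment: str, reference, min_score: float = DEFAULT_MIN_SCORE,
                k: int = DEFAULT_K, scoring: Optional[dict] = None,
                screen_max_frac: float = DEFAULT_SCREEN_MAX_FRAC
                ) -> List[HomologyHit]:
    """Rank all local alignments of ``fragment`` scoring >= ``min_score``.

    ``reference`` is a sequence of :class:`RefSeq` or a prebuilt
    :class:`ReferenceIndex`.  Candidate loci are screened on both strands
    by banded infix edit distance (edlib); loci within
    ``screen_max_frac`` * fragment length are extended by local alignment.
    The screen has no miss probability at the divergences the classifier
    must handle, unlike exact k-mer seeding, and chance matches fall far
    outside the threshold, so no E-value model is needed.  Ties are broken
    deterministically (shorter/lower chromosome label, then lower start).
    """
    if not fragment:
        raise InputError("empty fragment")
    if isinstance(reference, ReferenceIndex):
        index = reference
    else:
        refs = list(reference)
        if not refs:
            raise InputError("empty reference")
        index = ReferenceIndex(refs, k=k)
    import edlib

    aligner = _scoring_aligner(**(scoring or {}))
    frag_fwd = fragment.upper()
    frag_rev = str(Seq(frag_fwd).reverse_complement())
    max_dist = int(screen_max_frac * len(frag_fwd))
    hits: List[HomologyHit] = []
    for ref in index.refs:
        seq = ref.seq.upper()
        dists = {}
        for strand, frag in ((1, frag_fwd), (-1, frag_rev)):
            res = edlib.align(frag, seq, mode="HW", task="distance",
                              k=max_dist)
            if res["editDistance"] >= 0:
                dists[strand] = res["editDistance"]
        if not dists:
            continue
        best_dist = min(dists.values())
        best = None
        for strand, frag in ((1, frag_fwd), (-1, frag_rev)):
            if dists.get(strand, max_dist + 1) > best_dist:
                continue
            aln = aligner.align(seq, frag)[0]
            if best is None or aln.score > best[0]:
                best = (aln.score, strand, aln)
        score, strand, aln = best
        if score < min_score:
            continue
        identity, _cols, begin, end = _alignment_stats(aln)
        target = Anchor(ref.chrom, ref.start + begin, ref.start + end - 1)
        hits.append(HomologyHit(target=target, score=float(score),
                                identity=identity, strand=strand))
    hits.sort(key=lambda h: (-h.score, _chrom_sort_key(h.target.chrom),
                             h.target.start))
    for rank, hit in enumerate(hits, start=1):
        hit.rank = rank
    return hits


def find_paralog2(paralog1: RefSeq, reference,
                  min_score: float = DEFAULT_MIN_SCORE, k: int = DEFAULT_K
                  ) -> Optional[Anchor]:
    """Second-best non-self locus of a reference gene's own search, or None.

    Emulates the self-BLAST step that identifies the WGD partner: the best
    hit is the gene itself and is excluded even at identity 1.0; the next
    hit above threshold, if any, is the paralog-2 locus.
    """
    hits = search_hits(paralog1.seq, reference, min_score=min_score, k=k)
    for hit in hits:
        if hit.target.overlaps(paralog1.anchor):
            continue
        return hit.target
    return None


def classify_orthology(marker: MarkerRecord, hits: Sequence[HomologyHit],
                       synteny_table: Mapping[str, Set[str]],
                       paralog2: Optional[Anchor] = None) -> OrthologyCall:
    """Classify a marker from its ranked hits and map-position concordance.

    Decision rule, in order: (a) best hit overlaps the expected anchor ->
    ortholog_expected; (b) best hit overlaps the known paralog-2 locus ->
    ortholog_of_paralog2 when the marker's linkage group is a synteny
    partner of that chromosome, discordant_anomaly otherwise; (b2) when no
    paralog 2 is known but the off-anchor best hit lies on a partner
    chromosome of the marker's linkage group, the hit itself is taken as the
    paralog-2 locus; (d) anything else -> other_region.  Markers without a
    map position can only receive categories (a) and (d).
    """
    evidence: dict = {"n_hits": len(hits)}
    if not hits:
        return OrthologyCall(marker=marker.name, category=OTHER_REGION,
                             paralog1=marker.expected_anchor, paralog2=paralog2,
                             best_hit=None,
                             evidence={"n_hits": 0, "flagged_no_hits": True})
    best = hits[0]
    evidence["best_score"] = best.score
    evidence["best_identity"] = best.identity
    partners = set()
    if marker.linkage_group is not None:
        partners = set(synteny_table.get(marker.linkage_group, set()))
        evidence["lg_partners"] = sorted(partners)

    if best.target.overlaps(marker.expected_anchor):
        category = ORTHOLOG_EXPECTED
        evidence["anchor_overlap"] = True
    elif paralog2 is not None and best.target.overlaps(paralog2):
        evidence["paralog2_overlap"] = True
        if marker.linkage_group is None:
            category = OTHER_REGION
            evidence["no_map_position"] = True
        elif paralog2.chrom in partners:
            category = ORTHOLOG_OF_PARALOG2
            evidence["synteny_concordant"] = True
        else:
            category = DISCORDANT_ANOMALY
            evidence["synteny_concordant"] = False
    elif paralog2 is None and marker.linkage_group is not None \
            and best.target.chrom in partners:
        category = ORTHOLOG_OF_PARALOG2
        paralog2 = best.target
        evidence["paralog2_inferred_from_hit"] = True
        evidence["synteny_concordant"] = True
    else:
        category = OTHER_REGION
    return OrthologyCall(marker=marker.name, category=category,
                         paralog1=marker.expected_anchor, paralog2=paralog2,
                         best_hit=best.target, evidence=evidence)


def calls_to_frame(calls: Sequence[OrthologyCall]):
    """Tabulate calls in the published tables' column style."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({
            "marker": c.marker,
            "category": c.category,
            "paralog1": str(c.paralog1),
            "paralog2": str(c.paralog2) if c.paralog2 else "NA",
            "best_hit": str(c.best_hit) if c.best_hit else "NA",
            "identity": c.evidence.get("best_identity"),
        })
    return pd.DataFrame(rows)
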