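"""In-memory containers for simulated genomes and the simulator's truth log."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

ORTHOLOG = "ortholog"
CROSS_LINEAGE_PARALOG = "cross_lineage_paralog"
WITHIN_LINEAGE_PARALOG = "within_lineage_paralog"


@dataclass
class Gene:
    """One gene copy: an intron sequence anchored on a chromosome.

    ``ancestral_id`` identifies the pre-WGD ancestral gene; ``wgd_copy`` is 1
    or 2 for the two duplication products.  Coordinates are 1-based inclusive
    and assigned when the genome is finalized.
    """

    ancestral_id: int
    wgd_copy: int
    sequence: str
    strand: int = 1
    start: int = 0
    end: int = 0

    @property
    def key(self) -> Tuple[int, int]:
        return (self.ancestral_id, self.wgd_copy)


@dataclass
class Chromosome:
    name: str
    genes: List[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SimulatedGenome:
    lineage: str
    chromosomes: List[Chromosome] = field(default_factory=list)

    def finalize_coordinates(self, gene_spacing: int) -> None:
        """Place gene i of each chromosome at start = i*spacing + 1."""
        for chrom in self.chromosomes:
            for i, gene in enumerate(chrom.genes):
                gene.start = i * gene_spacing + 1
                gene.end = gene.start + len(gene.sequence) - 1
                if gene.end < gene.start:
                    raise ValueError("empty gene sequence")

    def genes(self) -> Iterator[Tuple[str, Gene]]:
        for chrom in self.chromosomes:
            for gene in chrom.genes:
                yield chrom.name, gene

    def gene_index(self) -> Dict[Tuple[int, int], Tuple[str, Gene]]:
        """Map (ancestral_id, wgd_copy) -> (chromosome name, gene)."""
        return {gene.key: (name, gene) for name, gene in self.genes()}

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)


@dataclass
class RearrangementRecord:
    """One injected event, as the simulator's ground truth."""

    lineage: str
    time_my: float
    type: str
    chromosomes: Tuple[str, ...]
    gene_keys: Tuple[Tuple[int, int], ...]
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lineage": self.lineage,
            "time_my": self.time_my,
            "type": self.type,
            "chromosomes": list(self.chromosomes),
            "gene_keys": [list(k) for k in self.gene_keys],
            "detail": self.detail,
        }


@dataclass
class TruthLog:
    """Ground truth of a simulated genome pair.

    Homology classes are implicit in the gene labels: the same
    (ancestral_id, wgd_copy) across genomes is an ortholog pair, different
    wgd_copy is a paralog pair (cross- or within-lineage).  True expected
    divergences follow 2*r*t for the relevant separation time.
    """

    t_wgd: float
    t_spec: float
    r: float
    events: List[RearrangementRecord] = field(default_factory=list)

    def homology_class(self, key_a: Tuple[int, int], key_b: Tuple[int, int],
                       same_genome: bool = False) -> Optional[str]:
        if key_a[0] != key_b[0]:
            return None
        if key_a[1] == key_b[1]:
            return None if same_genome else ORTHOLOG
        return WITHIN_LINEAGE_PARALOG if same_genome else CROSS_LINEAGE_PARALOG

    def true_divergence(self, homology: str) -> float:
        """Expected substitutions/site separating a pair of that class."""
        if homology == ORTHOLOG:
            return 2.0 * self.r * self.t_spec * 1e6
        if homology in (CROSS_LINEAGE_PARALOG, WITHIN_LINEAGE_PARALOG):
            return 2.0 * self.r * self.t_wgd * 1e6
        raise ValueError(f"unknown homology class {homology!r}")

    def events_for(self, lineage: str) -> List[RearrangementRecord]:
        return [e for e in self.events if e.lineage == lineage]

    def to_dict(self) -> dict:
        return {
            "t_wgd": self.t_wgd,
            "t_spec": self.t_spec,
            "r": self.r,
            "true_divergence": {
                ORTHOLOG: self.true_divergence(ORTHOLOG),
                CROSS_LINEAGE_PARALOG: self.true_divergence(CROSS_LINEAGE_PARALOG),
                WITHIN_LINEAGE_PARALOG: self.true_divergence(WITHIN_LINEAGE_PARALOG),
            },
            "events": [e.to_dict() for e in self.events],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
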