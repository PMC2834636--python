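"""File formats: located FASTA, anchor/marker TSV, genotype TSV, JSON.

Located FASTA records carry 1-based inclusive coordinates in the header,
``>chrom:start-end``; a header without coordinates locates the record at
position 1.  Anchor tables are TSV with columns marker, chrom, start, end,
strand (Table-style ``I:34332298-34337706`` coordinates split into fields).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import SimulatedGenome
from .homology import Anchor, RefSeq

_HEADER_RE = re.compile(r"^(?P<chrom>[^:\s]+)(?::(?P<start>\d+)-(?P<end>\d+))?$")


def parse_located_header(header: str) -> Tuple[str, Optional[int], Optional[int]]:
    m = _HEADER_RE.match(header.strip())
    if not m:
        raise ValueError(f"cannot parse located header {header!r}")
    start = int(m["start"]) if m["start"] else None
    end = int(m["end"]) if m["end"] else None
    return m["chrom"], start, end


def read_located_fasta(path) -> List[RefSeq]:
    refs = []
    for record in SeqIO.parse(str(path), "fasta"):
        chrom, start, end = parse_located_header(record.id)
        seq = str(record.seq).upper()
        if start is None:
            start, end = 1, len(seq)
        refs.append(RefSeq(chrom=chrom, start=start, end=end, seq=seq))
    return refs


def write_located_fasta(refs: Iterable[RefSeq], path) -> None:
    records = [SeqRecord(Seq(r.seq), id=f"{r.chrom}:{r.start}-{r.end}",
                         description="") for r in refs]
    SeqIO.write(records, str(path), "fasta")


def genome_refseqs(genome: SimulatedGenome) -> List[RefSeq]:
    """One located record per gene of a simulated genome."""
    return [RefSeq(chrom=name, start=g.start, end=g.end, seq=g.sequence)
            for name, g in genome.genes()]


def write_genome_fasta(genome: SimulatedGenome, path) -> None:
    write_located_fasta(genome_refseqs(genome), path)


def write_marker_fasta(markers: pd.DataFrame, path) -> None:
    records = [SeqRecord(Seq(row.fragment), id=row.marker, description="")
               for row in markers.itertuples()]
    SeqIO.write(records, str(path), "fasta")


ANCHOR_COLUMNS = ["marker", "chrom", "start", "end", "strand"]


def write_anchor_tsv(markers: pd.DataFrame, path) -> None:
    markers[ANCHOR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_anchor_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANCHOR_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"anchor table missing columns {sorted(missing)}")
    return df


def anchors_from_frame(df: pd.DataFrame) -> Dict[str, Anchor]:
    out = {}
    for row in df.itertuples():
        start = None if pd.isna(row.start) else int(row.start)
        end = None if pd.isna(row.end) else int(row.end)
        out[row.marker] = Anchor(str(row.chrom), start, end)
    return out


def write_genotype_tsv(genotypes: pd.DataFrame, marker_info: pd.DataFrame,
                       path) -> None:
    """Offspring x marker genotype table with a seg-type header row."""
    path = Path(path)
    header = pd.DataFrame(
        [marker_info.loc[genotypes.columns, "seg_type"]],
        index=["<seg_type>"])
    pd.concat([header, genotypes]).to_csv(path, sep="\t",
                                          index_label="individual")


def read_genotype_tsv(path) -> Tuple[pd.DataFrame, Dict[str, str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    seg = df.loc["<seg_type>"].to_dict()
    geno = df.drop(index="<seg_type>")
    return geno, seg


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
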