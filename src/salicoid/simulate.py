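"""Genome-pair simulator with known WGD/speciation history.

The generative model: an ancestral gene set (one intron sequence per gene,
genes spaced every ``gene_spacing`` bp on ``n_chromosomes`` chromosomes) is
duplicated in whole at ``t_wgd`` My (copy-2 chromosomes appended, no
immediate diploidization), the duplicated genome evolves to ``t_spec`` My,
splits into two lineages, and each lineage then accrues neutral
substitutions plus Poisson(event_rate * t_spec) chromosomal rearrangements
(fission, fusion, inversion, single-gene translocation in the proportions of
``event_mix``).  Every stochastic choice derives from ``params.seed``, so
identical parameters reproduce byte-identical genomes.

Substitutions follow a continuous-time Markov model on {A,C,G,T}: the
equal-frequency single-rate (Jukes-Cantor) default, or a two-transition-class
unequal-frequency (Tamura-Nei) mode.  Branch lengths are expected
substitutions/site, d = r * t(years), so a pair separated for t My shows
2*r*t*1e6 expected substitutions per site.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .genome import (Chromosome, Gene, RearrangementRecord, SimulatedGenome,
                     TruthLog)
from .linkage_stats import kosambi_inverse
from .maps import LinkageMap
from .params import EVENT_TYPES, EvolutionParams, ParameterError

BASES = np.array(list("ACGT"))
_A, _C, _G, _T = 0, 1, 2, 3

# sub-streams of params.seed, one per stochastic operation
_STREAM_SIM = 1
_STREAM_MARKERS = 2
_STREAM_MAP = 3
_STREAM_GENOTYPES = 4


def tn93_rate_matrix(base_freqs: Sequence[float], kappa_purine: float = 1.0,
                     kappa_pyrimidine: float = 1.0) -> np.ndarray:
    """Tamura-Nei rate matrix scaled to one expected substitution per unit time.

    ``kappa_purine`` and ``kappa_pyrimidine`` multiply the A<->G and C<->T
    exchange rates relative to transversions; with both equal to 1 and
    uniform frequencies this reduces to Jukes-Cantor.
    """
    pi = np.asarray(base_freqs, dtype=float)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if {i, j} == {_A, _G}:
                rate *= kappa_purine
            elif {i, j} == {_C, _T}:
                rate *= kappa_pyrimidine
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def _model_components(params: EvolutionParams) -> Tuple[np.ndarray, np.ndarray]:
    if params.subst_model == "jc":
        pi = np.full(4, 0.25)
        Q = tn93_rate_matrix(pi, 1.0, 1.0)
    else:
        pi = np.asarray(params.base_freqs, dtype=float)
        Q = tn93_rate_matrix(pi, params.kappa_purine, params.kappa_pyrimidine)
    return pi, Q


def evolve_indices(idx: np.ndarray, P: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Mutate a base-index array one branch, given transition matrix ``P``."""
    out = np.empty_like(idx)
    u = rng.random(idx.shape)
    cum = np.cumsum(P, axis=1)
    for state in range(4):
        mask = idx == state
        if mask.any():
            out[mask] = np.searchsorted(cum[state], u[mask], side="right")
    return np.minimum(out, 3)


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(BASES[idx])


def seq_to_indices(seq: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("non-ACGT residue in sequence")
    return arr.astype(np.int64)


# ---------------------------------------------------------------------------
# rearrangement machinery
# ---------------------------------------------------------------------------

def _apply_fission(chroms, rng, counter):
    cands = [i for i, c in enumerate(chroms) if len(c) >= 2]
    if not cands:
        return None
    i = cands[int(rng.integers(len(cands)))]
    old = chroms[i]
    cut = int(rng.integers(1, len(old)))
    n = next(counter)
    left = Chromosome(f"{old.name}.f{n}a", old.genes[:cut])
    right = Chromosome(f"{old.name}.f{n}b", old.genes[cut:])
    chroms[i:i + 1] = [left, right]
    return dict(type="fission",
                chromosomes=(old.name, left.name, right.name),
                gene_keys=(old.genes[cut - 1].key, old.genes[cut].key),
                detail={"cut_index": cut})


def _apply_fusion(chroms, rng, counter):
    if len(chroms) < 2:
        return None
    i, j = rng.choice(len(chroms), size=2, replace=False)
    i, j = int(i), int(j)
    a, b = chroms[i], chroms[j]
    fused = Chromosome(f"{a.name}+{b.name}", a.genes + b.genes)
    chroms[:] = [c for k, c in enumerate(chroms) if k not in (i, j)]
    chroms.append(fused)
    return dict(type="fusion",
                chromosomes=(a.name, b.name, fused.name),
                gene_keys=(a.genes[-1].key, b.genes[0].key),
                detail={})


def _apply_inversion(chroms, rng, counter, size_range):
    lo, hi = size_range
    cands = [i for i, c in enumerate(chroms) if len(c) >= max(2, lo)]
    if not cands:
        return None
    i = cands[int(rng.integers(len(cands)))]
    c = chroms[i]
    seg = int(rng.integers(lo, hi + 1))
    seg = min(seg, len(c))
    start = int(rng.integers(0, len(c) - seg + 1))
    block = c.genes[start:start + seg][::-1]
    for g in block:
        g.strand *= -1
    c.genes[start:start + seg] = block
    return dict(type="inversion",
                chromosomes=(c.name,),
                gene_keys=tuple(g.key for g in block),
                detail={"start_index": start, "size": seg})


def _apply_translocation(chroms, rng, counter):
    sources = [i for i, c in enumerate(chroms) if len(c) >= 2]
    if not sources or len(chroms) < 2:
        return None
    i = sources[int(rng.integers(len(sources)))]
    src = chroms[i]
    gi = int(rng.integers(len(src)))
    gene = src.genes.pop(gi)
    targets = [j for j in range(len(chroms)) if j != i]
    j = targets[int(rng.integers(len(targets)))]
    dst = chroms[j]
    pos = int(rng.integers(0, len(dst) + 1))
    dst.genes.insert(pos, gene)
    return dict(type="translocation",
                chromosomes=(src.name, dst.name),
                gene_keys=(gene.key,),
                detail={"source_index": gi, "target_index": pos})


_APPLIERS = {
    "fission": _apply_fission,
    "fusion": _apply_fusion,
    "translocation": _apply_translocation,
}


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def simulate_pair(params: EvolutionParams):
    """Simulate a genome pair with the given history.

    Returns ``(genome_focal, genome_reference, truth)`` where the focal
    genome stands in for the mapped species (willow) and the reference for
    the sequenced species (poplar).  Both lineages evolve independently after
    the split; rearrangements accrue only on the two post-split branches.
    """
    rng = np.random.default_rng([params.seed, _STREAM_SIM])
    pi, Q = _model_components(params)
    d_internal = params.r * (params.t_wgd - params.t_spec) * 1e6
    d_terminal = params.r * params.t_spec * 1e6
    P_internal = expm(Q * d_internal) if d_internal > 0 else np.eye(4)
    P_terminal = expm(Q * d_terminal) if d_terminal > 0 else np.eye(4)

    lo, hi = params.intron_length_range
    ancestral: list[list[np.ndarray]] = []
    gene_id = itertools.count(1)
    ids: list[list[int]] = []
    for _ in range(params.n_chromosomes):
        lengths = rng.integers(lo, hi + 1, size=params.genes_per_chromosome)
        seqs = [rng.choice(4, size=int(n), p=pi) for n in lengths]
        ancestral.append(seqs)
        ids.append([next(gene_id) for _ in seqs])

    # Copy-1 and copy-2 of a lineage share their duplication->split branch
    # history with the other lineage's same copy: evolve the internal branch
    # once per (copy, chromosome), then branch per lineage.
    chrom_states = {}
    for copy in (1, 2):
        for ci, seqs in enumerate(ancestral):
            chrom_states[(copy, ci)] = [
                evolve_indices(anc, P_internal, rng) for anc in seqs]

    genomes = {}
    truth = TruthLog(t_wgd=params.t_wgd, t_spec=params.t_spec, r=params.r)
    for lineage in ("S", "P"):
        chroms = []
        for copy in (1, 2):
            for ci in range(params.n_chromosomes):
                suffix = "" if copy == 1 else "d"
                name = f"{lineage}{ci + 1:02d}{suffix}"
                genes = []
                for gi, split_state in enumerate(chrom_states[(copy, ci)]):
                    tip = evolve_indices(split_state, P_terminal, rng)
                    genes.append(Gene(ancestral_id=ids[ci][gi], wgd_copy=copy,
                                      sequence=indices_to_seq(tip)))
                chroms.append(Chromosome(name, genes))
        genome = SimulatedGenome(lineage=lineage, chromosomes=chroms)

        n_events = int(rng.poisson(params.event_rate * params.t_spec))
        times = np.sort(rng.uniform(0.0, params.t_spec, size=n_events))[::-1]
        counter = itertools.count(1)
        for t_ev in times:
            etype = EVENT_TYPES[int(rng.choice(4, p=params.mix_vector))]
            if etype == "inversion":
                result = _apply_inversion(genome.chromosomes, rng, counter,
                                          params.inversion_size_range)
            else:
                result = _APPLIERS[etype](genome.chromosomes, rng, counter)
            if result is None:
                continue
            truth.events.append(RearrangementRecord(
                lineage=lineage, time_my=float(t_ev), **result))
        genome.finalize_coordinates(params.gene_spacing)
        genomes[lineage] = genome

    return genomes["S"], genomes["P"], truth


# ---------------------------------------------------------------------------
# marker panels and maps
# ---------------------------------------------------------------------------

def sample_markers(genome: SimulatedGenome, params: EvolutionParams,
                   spacing: Optional[int] = None) -> pd.DataFrame:
    """Sample one marker per gene at ~``spacing`` bp (default: every gene).

    The fragment is the gene's whole intron sequence, so its length is
    always within ``intron_length_range``.  With
    ``paralog_amplification_rate`` > 0, a fraction of markers emulates
    erroneous paralog amplification: the fragment is drawn from, and the
    marker segregates (and hence maps) at, the within-genome WGD
    counterpart of the sampled gene, while ``ancestral_id``/``wgd_copy``
    keep recording the designed target.  The true source is in the
    ``amplified_*`` columns.
    """
    if genome.n_genes == 0:
        raise ValueError("empty genome")
    step = 1
    if spacing is not None:
        step = max(1, int(round(spacing / params.gene_spacing)))
    rng = np.random.default_rng([params.seed, _STREAM_MARKERS])
    index = genome.gene_index()
    rows = []
    for chrom in genome.chromosomes:
        for j, gene in enumerate(chrom.genes):
            if j % step:
                continue
            fragment = gene.sequence
            amplified = gene.key
            located = (chrom.name, gene)
            if params.paralog_amplification_rate > 0 and \
                    rng.random() < params.paralog_amplification_rate:
                partner_key = (gene.ancestral_id, 3 - gene.wgd_copy)
                if partner_key in index:
                    located = index[partner_key]
                    fragment = located[1].sequence
                    amplified = partner_key
            loc_chrom, loc_gene = located
            rows.append({
                "marker": f"{chrom.name}_{j + 1}_sa",
                "chrom": loc_chrom,
                "start": loc_gene.start,
                "end": loc_gene.end,
                "strand": loc_gene.strand,
                "ancestral_id": gene.ancestral_id,
                "wgd_copy": gene.wgd_copy,
                "amplified_ancestral_id": amplified[0],
                "amplified_wgd_copy": amplified[1],
                "fragment": fragment,
            })
    return pd.DataFrame(rows)


def build_linkage_map(genome: SimulatedGenome, markers: pd.DataFrame,
                      params: EvolutionParams,
                      noise_sd: float = 0.0) -> LinkageMap:
    """Place markers on one linkage group per chromosome.

    cM = physical offset (Mb) * recomb_density + Gaussian jitter (sd in cM);
    markers are re-sorted by the jittered cM, so jitter can swap near-tied
    neighbours but the map stays monotone.  Each group is shifted to start
    at 0 cM.
    """
    if params.recomb_density < 0:
        raise ParameterError("recomb_density must be >= 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng([params.seed, _STREAM_MAP])
    groups = {}
    for chrom in genome.chromosomes:
        sub = markers[markers["chrom"] == chrom.name]
        if sub.empty:
            continue
        cm = (sub["start"].to_numpy(dtype=float) - 1) / 1e6 * params.recomb_density
        if noise_sd > 0:
            cm = cm + rng.normal(0.0, noise_sd, size=cm.size)
        order = np.argsort(cm, kind="stable")
        cm_sorted = cm[order] - cm[order[0]]
        cm_sorted = np.maximum.accumulate(cm_sorted)  # guard fp wiggle
        names = sub["marker"].to_numpy()[order]
        groups[f"LG_{chrom.name}"] = list(zip(names, cm_sorted.tolist()))
    return LinkageMap(groups)


# ---------------------------------------------------------------------------
# full-sib (CP) genotype simulation
# ---------------------------------------------------------------------------

#: informativeness mix of the published S1 SNP set:
#: 75 maternal-only, 158 paternal-only, 74 biparental.
DEFAULT_INFORMATIVENESS_MIX = (75 / 307, 158 / 307, 74 / 307)

_SEG_TYPES = ("lmxll", "nnxnp", "hkxhk")
_PARENT_GENOTYPES = {
    # seg type -> (mother alleles, father alleles)
    "lmxll": (("l", "m"), ("l", "l")),
    "nnxnp": (("n", "n"), ("n", "p")),
    "hkxhk": (("h", "k"), ("h", "k")),
}


def simulate_cp_genotypes(lmap: LinkageMap, n_offspring: int,
                          informativeness_mix=DEFAULT_INFORMATIVENESS_MIX,
                          seed: int = 0):
    """Simulate a full-sib family on a linkage map.

    Markers are assigned maternal-only (lmxll), paternal-only (nnxnp) or
    biparental (hkxhk) configurations in the given proportions, with random
    linkage phase per parent.  Offspring gametes follow a no-interference
    crossover process: adjacent-interval recombination fractions are the
    inverse Kosambi transform of the map distance, chained as a Markov
    process along each group and independent between groups and parents.

    Returns ``(genotypes, marker_info)``: an offspring x marker DataFrame of
    genotype codes (ll/lm, nn/np, hh/hk/kk) and a per-marker table with
    segregation type, map position and simulated phases.
    """
    if n_offspring < 1:
        raise ParameterError("n_offspring must be >= 1")
    mix = np.asarray(informativeness_mix, dtype=float)
    if mix.size != 3 or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise ParameterError("informativeness_mix must be 3 proportions summing to 1")
    rng = np.random.default_rng([seed, _STREAM_GENOTYPES])

    info_rows = []
    geno_cols = {}
    for group, entries in lmap.groups.items():
        names = [m for m, _ in entries]
        cms = np.array([cm for _, cm in entries], dtype=float)
        seg = [_SEG_TYPES[int(k)] for k in rng.choice(3, size=len(names), p=mix)]
        phase_m = rng.integers(0, 2, size=len(names))
        phase_p = rng.integers(0, 2, size=len(names))

        rf = kosambi_inverse(np.diff(cms)) if len(cms) > 1 else np.array([])
        hap = {}
        for parent in ("m", "p"):
            H = np.empty((n_offspring, len(names)), dtype=np.int8)
            H[:, 0] = rng.integers(0, 2, size=n_offspring)
            for i, r in enumerate(rf):
                rec = rng.random(n_offspring) < r
                H[:, i + 1] = H[:, i] ^ rec
            hap[parent] = H

        for i, name in enumerate(names):
            mother, father = _PARENT_GENOTYPES[seg[i]]
            if mother[0] != mother[1]:
                mat = np.array(mother)[(hap["m"][:, i] + phase_m[i]) % 2]
            else:
                mat = np.full(n_offspring, mother[0])
            if father[0] != father[1]:
                pat = np.array(father)[(hap["p"][:, i] + phase_p[i]) % 2]
            else:
                pat = np.full(n_offspring, father[0])
            geno_cols[name] = ["".join(sorted((a, b)))
                               for a, b in zip(mat, pat)]
            info_rows.append({
                "marker": name, "linkage_group": group, "cM": cms[i],
                "seg_type": seg[i], "phase_m": int(phase_m[i]),
                "phase_p": int(phase_p[i]),
            })

    offspring = [f"off{i + 1:04d}" for i in range(n_offspring)]
    genotypes = pd.DataFrame(geno_cols, index=offspring)
    marker_info = pd.DataFrame(info_rows).set_index("marker")
    return genotypes, marker_info
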