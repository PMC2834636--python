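"""Simulation parameters for the genome-pair generator.

All times are million years before present (My); the substitution rate ``r``
is per site per *year*.  The only place the 10**6 unit conversion happens is
the :mod:`salicoid.dating` module and the internal branch-length computation
of the simulator, both of which take My in and hand substitutions/site out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Tuple

EVENT_TYPES = ("fission", "fusion", "inversion", "translocation")

#: Event-type proportions matching the observed split of 13 events between the
#: two Salicaceae lineages: one fission, one fusion, five inversions, six
#: single-marker translocations.
DEFAULT_EVENT_MIX = {
    "fission": 1 / 13,
    "fusion": 1 / 13,
    "inversion": 5 / 13,
    "translocation": 6 / 13,
}


class ParameterError(ValueError):
    """Raised for invalid evolutionary parameters."""


@dataclass
class EvolutionParams:
    """Parameters of the two-lineage, post-WGD evolutionary scenario.

    Defaults reproduce the Salicaceae study conditions: a whole-genome
    duplication 150 My ago, a lineage split 45 My ago, a neutral intron
    substitution rate of 1.3e-9 per site per year, a rearrangement rate of
    0.14 events/My/genome per lineage, markers every 1 Mb with 500-1000 bp
    intron fragments, and a map density of 5 cM/Mb (the published map's mean
    marker interval at 1 Mb spacing).
    """

    t_wgd: float = 150.0          # My, whole-genome duplication
    t_spec: float = 45.0          # My, lineage split; must be < t_wgd
    r: float = 1.3e-9             # substitutions / site / year
    event_rate: float = 0.14      # rearrangements / My / genome / lineage
    event_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    n_chromosomes: int = 19
    genes_per_chromosome: int = 35
    gene_spacing: int = 1_000_000  # bp between sampled genes
    intron_length_range: Tuple[int, int] = (500, 1000)
    recomb_density: float = 5.0   # cM / Mb
    seed: int = 0

    # substitution-model knobs; "jc" is the equal-frequency single-rate
    # default, "tn93" enables two transition classes + unequal frequencies so
    # the distance estimator can be exercised off its null.
    subst_model: str = "jc"
    base_freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa_purine: float = 2.0     # A<->G rate multiplier (tn93 mode)
    kappa_pyrimidine: float = 4.0  # C<->T rate multiplier (tn93 mode)

    # fraction of markers whose fragment is (erroneously) amplified from the
    # within-genome WGD copy 2, emulating paralog amplification.
    paralog_amplification_rate: float = 0.0

    # inversions reverse this many consecutive genes (inclusive bounds).
    inversion_size_range: Tuple[int, int] = (3, 8)

    def __post_init__(self) -> None:
        if not self.t_spec < self.t_wgd:
            raise ParameterError(
                f"t_spec ({self.t_spec}) must be < t_wgd ({self.t_wgd})")
        if self.t_spec <= 0 or self.t_wgd <= 0:
            raise ParameterError("times must be positive")
        if self.r < 0:
            raise ParameterError("substitution rate r must be >= 0")
        if self.event_rate < 0:
            raise ParameterError("event_rate must be >= 0")
        mix = dict(self.event_mix)
        unknown = set(mix) - set(EVENT_TYPES)
        if unknown:
            raise ParameterError(f"unknown event types in mix: {unknown}")
        if any(v < 0 for v in mix.values()):
            raise ParameterError("event_mix proportions must be >= 0")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"event_mix must sum to 1 (got {total})")
        for name in ("n_chromosomes", "genes_per_chromosome", "gene_spacing"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        lo, hi = self.intron_length_range
        if not (1 <= lo <= hi):
            raise ParameterError("invalid intron_length_range")
        if self.recomb_density < 0:
            raise ParameterError("recomb_density must be >= 0")
        if self.subst_model not in ("jc", "tn93"):
            raise ParameterError("subst_model must be 'jc' or 'tn93'")
        freqs = tuple(self.base_freqs)
        if len(freqs) != 4 or any(f <= 0 for f in freqs) or \
                abs(sum(freqs) - 1.0) > 1e-9:
            raise ParameterError("base_freqs must be 4 positive values summing to 1")
        if not 0.0 <= self.paralog_amplification_rate <= 1.0:
            raise ParameterError("paralog_amplification_rate must be in [0, 1]")

    @property
    def mix_vector(self):
        return [dict(self.event_mix).get(t, 0.0) for t in EVENT_TYPES]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["event_mix"] = dict(self.event_mix)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EvolutionParams":
        d = dict(d)
        for key in ("intron_length_range", "base_freqs", "inversion_size_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
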