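"""Simulation configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

MECHANISMS = ("tandem_dup", "ectopic_ins", "te_ins", "deletion", "mixed")
LINEAGES = ("A", "B", "outgroup")

#: Variant classes used throughout selection analyses.
VARIANT_CLASSES = (
    "exonic_SV",
    "intronic_SV",
    "intergenic_SV",
    "stop_gain_SNP",
    "nonsyn_SNP",
    "syn_SNP",
)


@dataclass(frozen=True)
class EventSpec:
    """One planted structural event.

    lineage : which genome mutates ("A", "B", or "outgroup"; outgroup events
        are truth-ambiguous and must be discarded downstream).
    mechanism : tandem_dup | ectopic_ins | te_ins | deletion | mixed.
    length : event size in bp (>50 for genuine SVs).  For te_ins the actual
        inserted length is the closest toy TE family length.
    insertion_fraction : for "mixed" only — fraction of the event region made
        of novel (derived) bases, i.e. the expected gap-coverage value.
    """

    lineage: str
    mechanism: str
    length: int
    insertion_fraction: float = 0.5

    def __post_init__(self):
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.length <= 0:
            raise ValueError("event length must be positive")
        if not 0.0 <= self.insertion_fraction <= 1.0:
            raise ValueError("insertion_fraction must be in [0, 1]")


@dataclass
class SimConfig:
    """All knobs for one simulation run; a fixed seed makes output byte-identical."""

    genome_length: int = 100_000
    gc_content: float = 0.43
    event_spec: list[EventSpec] = field(default_factory=list)
    n_varieties: int = 101
    year_range: tuple[int, int] = (1905, 2013)
    selection_coeffs: dict[str, float] = field(default_factory=dict)
    sweep_s: float = 0.0
    selfing_rate: float = 0.95
    recomb_rate: float = 1e-5  # per bp per outcross meiosis (scaled-down genome)
    depth: float = 40.0
    read_length: int = 100
    seed: int = 0
    # secondary knobs
    n_generations: int = 28
    pop_size: int = 100
    n_founder_haplotypes: int = 8
    snp_count: int = 120
    ingroup_snp_rate: float = 0.001
    outgroup_snp_rate: float = 0.005
    softclip_prob: float = 0.9
    hemizygous_rate: float = 0.0
    #: generation at which the sweep allele is introgressed (None: mid-course)
    sweep_intro_generation: int | None = None
    #: founding-haplotype LD window in bp; 0 draws founder alleles
    #: independently per locus (no block structure at founding)
    founder_ld_window_bp: int = 10_000

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("gc_content", "selfing_rate", "softclip_prob", "hemizygous_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        self.event_spec = [
            e if isinstance(e, EventSpec) else EventSpec(**e) for e in self.event_spec
        ]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "year_range" in raw:
            raw["year_range"] = tuple(raw["year_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["year_range"] = list(d["year_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
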