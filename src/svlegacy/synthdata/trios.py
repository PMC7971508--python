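"""Parent/progeny trios from an inbred cohort.

The progeny of two fully inbred parents is itself taken to an inbred state:
at each locus it carries one parent's allele, chosen per recombination block
(Poisson breakpoints along the chromosome).  With probability `miscall_rate`
the recorded progeny call is flipped, emulating genotyping error; flipping at
a non-segregating locus produces a detectable "matches neither parent" call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort


@dataclass
class Trio:
    progeny_id: str
    parent1_id: str
    parent2_id: str
    parent1: np.ndarray
    parent2: np.ndarray
    progeny: np.ndarray


def simulate_trios(
    cohort: Cohort,
    n_trios: int,
    miscall_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[Trio]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(cohort.genotypes.index)
    if n_trios > len(ids) // 2:
        raise ValueError("n_trios exceeds available parent pairs")
    positions = cohort.loci["position"].to_numpy()
    genome_length = int(positions.max()) + 1 if len(positions) else 1
    order = rng.permutation(len(ids))
    trios = []
    for t in range(n_trios):
        i1, i2 = order[2 * t], order[2 * t + 1]
        h1 = cohort.genotypes.iloc[i1].to_numpy()
        h2 = cohort.genotypes.iloc[i2].to_numpy()
        n_break = rng.poisson(max(1.0, 1e-5 * genome_length))
        breaks = np.sort(rng.integers(0, genome_length, size=n_break))
        seg = np.searchsorted(breaks, positions, side="right")
        first = int(rng.random() < 0.5)
        child = np.where((seg + first) % 2 == 0, h1, h2).astype(np.int8)
        flips = rng.random(child.size) < miscall_rate
        child = np.where(flips, 1 - child, child).astype(np.int8)
        trios.append(
            Trio(
                progeny_id=f"trio{t:02d}_progeny",
                parent1_id=ids[i1],
                parent2_id=ids[i2],
                parent1=h1.astype(np.int8),
                parent2=h2.astype(np.int8),
                progeny=child,
            )
        )
    return trios
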