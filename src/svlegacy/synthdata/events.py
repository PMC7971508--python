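"""Plant structural events of known mechanism and emit the exact alignment.

The triple alignment is constructed directly from the edit script, so planted
breakpoints are exact by construction; no aligner is involved.  Lineage
backgrounds additionally carry i.i.d. substitutions (a low rate for the two
ingroups, a higher one for the outgroup) so that flank- and region-identity
filters are exercised realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..alignment import TripleAlignment
from .config import EventSpec, SimConfig
from .sequences import BASES, _random_seq, nearest_te_family

FLANK = 50
#: events must be separated by at least 2 x flank plus margin so that
#: candidate flanks never contain another event's gap columns
MIN_SPACING = 4 * FLANK + 50

_ROW_OF = {"A": 0, "B": 1, "outgroup": 2}


@dataclass
class PlantedEvent:
    """Ground truth for one planted event."""

    lineage: str
    mechanism: str
    length: int                      # net |derived - ancestral| bp
    anc_interval: tuple[int, int]    # on the (unobserved) ancestor
    derived_interval: tuple[int, int]  # on the mutated lineage's genome
    col_interval: tuple[int, int]    # alignment columns of the event region
    intervals: dict = field(default_factory=dict)  # per-row genome intervals
    inserted_seq: str = ""
    deleted_seq: str = ""
    g_true: float = 1.0
    ambiguous: bool = False          # outgroup-private: unpolarizable

    @property
    def expected_class(self) -> str:
        if self.g_true > 0.95:
            return "insertion"
        if self.g_true < 0.05:
            return "deletion"
        if 0.49 <= self.g_true <= 0.51:
            return "dropped_balanced"
        return "mixed"


@dataclass
class SimTruth:
    """Everything the downstream stages are scored against."""

    events: list[PlantedEvent]
    chrom: str = "chr1"
    sweep_locus: int | None = None

    @property
    def ingroup_events(self) -> list[PlantedEvent]:
        return [e for e in self.events if not e.ambiguous]

    def net_gain(self, lineage: str) -> int:
        """Sum of (derived - ancestral) bp over non-ambiguous events of a lineage."""
        total = 0
        for e in self.ingroup_events:
            if e.lineage == lineage:
                total += len(e.inserted_seq) - len(e.deleted_seq)
        return total


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions at `rate`, never back to the same base."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hits:
        alt = BASES[BASES != out[i]]
        out[i] = rng.choice(alt)
    return out


def _event_geometry(spec: EventSpec, te_cache: dict) -> tuple[int, int, int]:
    """(ancestral bp consumed, derived bp introduced, template bp upstream)."""
    if spec.mechanism == "deletion":
        return spec.length, 0, 0
    if spec.mechanism == "tandem_dup":
        return 0, spec.length, spec.length
    if spec.mechanism == "ectopic_ins":
        return 0, spec.length, 0
    if spec.mechanism == "te_ins":
        name, seq = nearest_te_family(spec.length)
        te_cache[id(spec)] = (name, seq)
        return 0, len(seq), 0
    # mixed: replace L_anc ancestral bases by L_der novel bases
    l_der = int(round(spec.insertion_fraction * spec.length))
    l_der = min(max(l_der, 0), spec.length)
    return spec.length - l_der, l_der, 0


def _place_events(
    specs: list[EventSpec], genome_length: int, te_cache: dict, rng: np.random.Generator
) -> list[int]:
    """Anchor positions on the ancestor, rejection-sampled for spacing."""
    geoms = [_event_geometry(s, te_cache) for s in specs]
    order = rng.permutation(len(specs))
    anchors: list[int | None] = [None] * len(specs)
    taken: list[tuple[int, int]] = []
    for idx in order:
        anc_len, _, template = geoms[idx]
        lo = MIN_SPACING + template
        hi = genome_length - MIN_SPACING - anc_len
        if hi <= lo:
            raise ValueError("event does not fit in the remaining sequence")
        for _ in range(2_000):
            p = int(rng.integers(lo, hi))
            foot = (p - template - MIN_SPACING, p + anc_len + MIN_SPACING)
            if all(foot[1] <= s or foot[0] >= e for s, e in taken):
                taken.append(foot)
                anchors[idx] = p
                break
        else:
            raise ValueError("could not place events without overlap; reduce count or lengths")
    return [int(a) for a in anchors]  # type: ignore[arg-type]


def plant_events(
    ancestor: str,
    spec: list[EventSpec] | SimConfig,
    seed: int | np.random.Generator = 0,
    chrom: str = "chr1",
    ingroup_snp_rate: float = 0.001,
    outgroup_snp_rate: float = 0.005,
):
    """Apply planted events to three lineages descending from `ancestor`.

    Returns
    -------
    (seqA, seqB, seqOut, TripleAlignment, SimTruth)
        Derived genome sequences, the exact column alignment, and the truth
        table.  Outgroup-lineage events are recorded as truth-ambiguous.
    """
    if isinstance(spec, SimConfig):
        specs = list(spec.event_spec)
        ingroup_snp_rate = spec.ingroup_snp_rate
        outgroup_snp_rate = spec.outgroup_snp_rate
    else:
        specs = list(spec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    anc = np.frombuffer(ancestor.encode(), dtype="S1")
    te_cache: dict = {}
    anchors = _place_events(specs, len(anc), te_cache, rng)

    # per-lineage substituted backgrounds (no indels yet)
    bg = [
        _mutate(anc, ingroup_snp_rate, rng),
        _mutate(anc, ingroup_snp_rate, rng),
        _mutate(anc, outgroup_snp_rate, rng),
    ]

    events = sorted(zip(anchors, specs), key=lambda t: t[0])
    rows: list[list[bytes]] = [[], [], []]
    anc2col = np.empty(len(anc) + 1, dtype=np.int64)
    truth: list[PlantedEvent] = []
    col = 0
    prev = 0
    gpos = [0, 0, 0]  # running ungapped position per row

    def _emit_ancestral(a: int, b: int) -> None:
        nonlocal col
        n = b - a
        if n <= 0:
            return
        for r in range(3):
            rows[r].append(bg[r][a:b].tobytes())
            gpos[r] += n
        anc2col[a:b] = np.arange(col, col + n)
        col += n

    for p, sp in events:
        _emit_ancestral(prev, p)
        row = _ROW_OF[sp.lineage]
        anc_len, der_len, template = _event_geometry(sp, te_cache)
        col_start = col
        der_start = gpos[row]
        deleted = anc[p : p + anc_len].tobytes().decode() if anc_len else ""
        # deleted bases: shown by the two non-mutated rows, gapped in the mutated row
        if anc_len:
            for r in range(3):
                if r == row:
                    rows[r].append(b"-" * anc_len)
                else:
                    rows[r].append(bg[r][p : p + anc_len].tobytes())
                    gpos[r] += anc_len
            anc2col[p : p + anc_len] = np.arange(col, col + anc_len)
            col += anc_len
        # inserted bases: carried by the mutated row only
        inserted = ""
        if der_len:
            if sp.mechanism == "tandem_dup":
                ins = bg[row][p - template : p].tobytes()
            elif sp.mechanism == "te_ins":
                ins = te_cache[id(sp)][1].encode()
            else:  # ectopic_ins or the novel part of mixed
                ins = _random_seq(der_len, 0.5, rng).encode()
            inserted = ins.decode()
            for r in range(3):
                if r == row:
                    rows[r].append(ins)
                else:
                    rows[r].append(b"-" * der_len)
            gpos[row] += der_len
            col += der_len
        g_true = der_len / (der_len + anc_len) if (der_len + anc_len) else 1.0
        truth.append(
            PlantedEvent(
                lineage=sp.lineage,
                mechanism=sp.mechanism,
                length=abs(der_len - anc_len),
                anc_interval=(p, p + anc_len),
                derived_interval=(der_start, der_start + der_len),
                col_interval=(col_start, col),
                inserted_seq=inserted,
                deleted_seq=deleted,
                g_true=g_true,
                ambiguous=sp.lineage == "outgroup",
            )
        )
        prev = p + anc_len
    _emit_ancestral(prev, len(anc))
    anc2col[len(anc)] = col

    texts = ["".join(part.decode() for part in r) for r in rows]
    aln = TripleAlignment(chrom=chrom, rows=(texts[0], texts[1], texts[2]))
    for ev in truth:
        ev.intervals = {
            name: aln.seq_interval(r, *ev.col_interval)
            for r, name in enumerate(("A", "B", "outgroup"))
        }
    st = SimTruth(events=truth, chrom=chrom)
    return aln.ungapped(0), aln.ungapped(1), aln.ungapped(2), aln, st
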