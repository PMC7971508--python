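"""Transposable-element consensus families and SV TE content.

Full-length copies of candidate elements are located in a genome (97% length
coverage at 95% identity), near-identical sequences are paired by reciprocal
overlap and consolidated into clusters, each cluster is multiply aligned and
summarized by a majority-rule consensus, and inserted SV sequence is then
annotated for the fraction of bases covered by family consensus hits.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import edlib
import networkx as nx
import numpy as np
import pandas as pd

GAPB = ord("-")


# ---------------------------------------------------------------- hit finding

def find_full_length_hits(
    te: str,
    genome: str,
    min_cov: float = 0.97,
    min_ident: float = 0.95,
    claimed: list[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Genomic intervals where `te` aligns near-full-length.

    Infix (semi-global) alignment of the element against the genome accepts a
    hit when the edit distance stays within the combined length-coverage and
    identity budget; hits are harvested best-first with masking, and intervals
    overlapping an already `claimed` region are skipped (first-come claiming —
    order across elements matters and is the caller's responsibility).
    `claimed` is extended in place when supplied.
    """
    if claimed is None:
        claimed = []
    max_dist = int(len(te) * ((1.0 - min_ident) + (1.0 - min_cov)))
    work = genome
    hits: list[tuple[int, int]] = []
    while True:
        res = edlib.align(te, work, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0 or not res["locations"]:
            break
        s, e = res["locations"][0]
        e += 1  # edlib locations are inclusive
        if not any(s < ce and cs < e for cs, ce in claimed):
            hits.append((s, e))
            claimed.append((s, e))
        work = work[:s] + "N" * (e - s) + work[e:]
    hits.sort()
    return hits


def scan_genome(
    tes: dict[str, str], genome: str, min_cov: float = 0.97, min_ident: float = 0.95
) -> pd.DataFrame:
    """Hit table for a set of elements, claiming genomic intervals in input order."""
    claimed: list[tuple[int, int]] = []
    rows = []
    for name, te in tes.items():
        for s, e in find_full_length_hits(te, genome, min_cov, min_ident, claimed):
            rows.append({"te": name, "start": s, "end": e})
    return pd.DataFrame(rows, columns=["te", "start", "end"])


# ------------------------------------------------------------------ clustering

def _reciprocal_overlap(a: str, b: str) -> tuple[float, float]:
    """Fraction of each sequence covered by matched columns of a global alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    matched = nice["matched_aligned"].count("|")
    return matched / len(a), matched / len(b)


def pair_and_cluster(
    seqs: dict[str, str], min_recip_overlap: float = 0.90, method: str = "components"
) -> list[list[str]]:
    """Cluster sequences whose reciprocal aligned coverage is >= the threshold.

    Pairs form the edges of a graph; clusters are its connected components.
    ``method="mcl"`` instead runs Markov clustering (inflation 2) on the
    adjacency matrix, which can split weakly chained components.
    """
    names = list(seqs)
    if not names:
        raise ValueError("no sequences to cluster")
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            ca, cb = _reciprocal_overlap(seqs[na], seqs[nb])
            if ca >= min_recip_overlap and cb >= min_recip_overlap:
                g.add_edge(na, nb)
    if method == "components":
        comps = [sorted(c) for c in nx.connected_components(g)]
    elif method == "mcl":
        comps = _mcl(g, names)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def _mcl(g: nx.Graph, names: list[str], inflation: float = 2.0, iters: int = 60) -> list[list[str]]:
    m = nx.to_numpy_array(g, nodelist=names) + np.eye(len(names))
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(iters):
        m = np.linalg.matrix_power(m, 2)
        m = m ** inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < 1e-12] = 0.0
    attractors = np.flatnonzero(np.diag(m) > 1e-6)
    clusters = []
    seen: set[int] = set()
    for a in attractors:
        members = set(np.flatnonzero(m[a] > 1e-6)) | {a}
        members -= seen
        if members:
            seen |= members
            clusters.append(sorted(names[i] for i in members))
    for i, n in enumerate(names):
        if n not in {x for c in clusters for x in c}:
            clusters.append([n])
    return clusters


# ------------------------------------------------------------------- consensus

def align_members(seqs: list[str]) -> list[str]:
    """Multiple alignment of cluster members (mafft; trivial for one member)."""
    if not seqs:
        raise ValueError("empty cluster")
    if len(seqs) == 1:
        return list(seqs)
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        fa = Path(td) / "in.fa"
        fa.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
        res = subprocess.run(
            ["mafft", "--quiet", "--retree", "2", str(fa)],
            capture_output=True, text=True, check=True,
        )
    out: list[str] = []
    for chunk in res.stdout.split(">")[1:]:
        lines = chunk.splitlines()
        out.append("".join(lines[1:]).upper())
    return out


def consensus(aligned: list[str]) -> str:
    """Majority-rule consensus of equal-length gapped sequences.

    Each column is called as its most frequent symbol among A, C, G, T and
    gap; gap-plurality columns are deleted.  Ties break by the fixed order
    A < C < G < T < gap.
    """
    if not aligned:
        raise ValueError("empty alignment")
    if len({len(s) for s in aligned}) != 1:
        raise ValueError("unequal gapped lengths")
    arr = np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in aligned])
    order = np.frombuffer(b"ACGT-", dtype=np.uint8)
    counts = np.stack([(arr == sym).sum(axis=0) for sym in order])  # 5 x ncols
    winner = counts.argmax(axis=0)  # argmax takes the first (tie order A<C<G<T<gap)
    keep = winner < 4
    return bytes(order[winner[keep]]).decode()


def build_families(
    seqs: dict[str, str], min_recip_overlap: float = 0.90, method: str = "components"
) -> pd.DataFrame:
    """Cluster candidate full-length copies and emit one consensus per family."""
    rows = []
    for i, members in enumerate(pair_and_cluster(seqs, min_recip_overlap, method)):
        cons = consensus(align_members([seqs[m] for m in members]))
        rows.append(
            {
                "family_id": f"FAM{i:04d}",
                "consensus": cons,
                "length": len(cons),
                "n_members": len(members),
                "members": ",".join(members),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- TE content

def te_fraction(inserted: str, families: dict[str, str], min_ident: float = 0.95) -> float:
    """Fraction of inserted bases covered by family consensus hits."""
    if not inserted:
        return 0.0
    intervals: list[tuple[int, int]] = []
    for cons in families.values():
        if len(cons) <= len(inserted):
            k = int(len(cons) * (1.0 - min_ident) + 3)
            work = inserted
            while True:
                res = edlib.align(cons, work, mode="HW", task="locations", k=k)
                if res["editDistance"] < 0 or not res["locations"]:
                    break
                s, e = res["locations"][0]
                intervals.append((s, e + 1))
                work = work[:s] + "N" * (e + 1 - s) + work[e + 1 :]
        else:
            k = int(len(inserted) * (1.0 - min_ident) + 3)
            res = edlib.align(inserted, cons, mode="HW", task="distance", k=k)
            if res["editDistance"] >= 0:
                intervals.append((0, len(inserted)))
    if not intervals:
        return 0.0
    intervals.sort()
    covered, hi = 0, 0
    for s, e in intervals:
        s = max(s, hi)
        if e > s:
            covered += e - s
            hi = e
        hi = max(hi, e)
    return covered / len(inserted)


def annotate_sv_te_content(
    svs, families: dict[str, str], min_event_fraction: float = 0.9
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-insertion TE fraction plus cohort-level summary.

    The summary reports the TE share of total inserted length and the share
    of insertion events that are directly TE-mediated (covered fraction >=
    `min_event_fraction`).
    """
    rows = []
    for i, sv in enumerate(svs):
        ins = sv.derived_seq if hasattr(sv, "derived_seq") else sv
        frac = te_fraction(ins, families)
        rows.append({"sv": i, "inserted_bp": len(ins), "te_fraction": frac})
    df = pd.DataFrame(rows)
    total = float(df["inserted_bp"].sum())
    summary = {
        "te_share_of_inserted_length": (
            float((df["inserted_bp"] * df["te_fraction"]).sum() / total) if total else 0.0
        ),
        "te_share_of_events": (
            float((df["te_fraction"] >= min_event_fraction).mean()) if len(df) else 0.0
        ),
    }
    return df, summary
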