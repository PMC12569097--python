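"""Fragment-based validation of clade-level read placement.

Full-length reference sequences are cut into read-length fragments and
re-placed against the labelled references; sensitivity (ingroup
fragments recovered into the ingroup) and specificity (one minus the
fraction of outgroup fragments placed into the ingroup) summarize how
reliably short reads are assigned to clades. The built-in placer is a
nearest-reference identity classifier (k-mer-seeded ungapped
alignment); the summary statistics are placer-agnostic and also accept
externally produced placements.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("denitscape")

DEFAULT_FRAGMENT_LENGTH = 150
KMER_SIZE = 8
LOW_IDENTITY = 0.5


@dataclass(frozen=True)
class FragmentRecord:
    fragment_id: str
    parent_id: str
    truth_label: str
    sequence: str


@dataclass(frozen=True)
class ValidationSummary:
    gene_family: str
    clade: str
    sensitivity: float
    specificity: float
    n_ingroup: int
    n_outgroup: int


def fragment_sequences(
    sequences: Iterable,
    truth: Mapping[str, str],
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    min_tail_fraction: float = 1 / 3,
) -> list[FragmentRecord]:
    """Cut sequences into non-overlapping read-length windows.

    Windows tile from the start; when the leftover tail is at least
    ``min_tail_fraction`` of a fragment (one third by default), a final
    window anchored at the sequence end is added (it overlaps the
    previous one). Sequences
    shorter than one fragment are skipped with a warning. ``truth`` maps
    each sequence id to its clade label; fragments inherit it.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    fragments: list[FragmentRecord] = []
    for rec in sequences:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        seq_id = rec.id if hasattr(rec, "id") else truth and next(iter(truth))
        if len(seq) < fragment_length:
            logger.warning(
                "sequence %s (%d nt) shorter than fragment length %d; skipped",
                seq_id, len(seq), fragment_length,
            )
            continue
        label = truth[seq_id]
        n_full = len(seq) // fragment_length
        starts = [i * fragment_length for i in range(n_full)]
        remainder = len(seq) - n_full * fragment_length
        if remainder >= min_tail_fraction * fragment_length:
            starts.append(len(seq) - fragment_length)
        for k, start in enumerate(starts):
            fragments.append(
                FragmentRecord(
                    fragment_id=f"{seq_id}|frag{k}",
                    parent_id=seq_id,
                    truth_label=label,
                    sequence=seq[start : start + fragment_length],
                )
            )
    return fragments


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _best_identity(
    frag: np.ndarray,
    ref: np.ndarray,
    ref_kmers: Mapping[bytes, list[int]],
    k: int = KMER_SIZE,
) -> float:
    """Best ungapped identity between fragment and reference.

    Candidate alignment offsets are seeded by shared k-mers; each
    offset's identity is the fraction of fragment positions matching the
    reference. Returns 0 when no k-mer is shared.
    """
    frag_bytes = frag.tobytes()
    offsets = set()
    for i in range(0, len(frag_bytes) - k + 1):
        for j in ref_kmers.get(frag_bytes[i : i + k], ()):
            offsets.add(j - i)
    best = 0.0
    n = len(frag)
    for off in offsets:
        lo = max(0, -off)
        hi = min(n, len(ref) - off)
        if hi <= lo:
            continue
        matches = int(np.count_nonzero(frag[lo:hi] == ref[off + lo : off + hi]))
        best = max(best, matches / n)
    return best


def nearest_reference_place(
    fragments: Sequence[FragmentRecord],
    references: Iterable,
    reference_clades: Mapping[str, str],
    k: int = KMER_SIZE,
) -> pd.DataFrame:
    """Place each fragment on the clade of its most similar reference.

    Every fragment is scored against every reference by the best
    ungapped k-mer-seeded alignment identity; the top-scoring clade
    receives mass 1.0, split equally between clades on exact score
    ties. Outgroup references compete on equal footing. Returns a tidy
    placement frame (read_id, clade, mass, best_identity, low_identity).
    """
    refs = []
    for rec in references:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        ref_id = rec.id if hasattr(rec, "id") else None
        if ref_id not in reference_clades:
            raise ValueError(f"reference {ref_id!r} has no clade label")
        arr = _seq_array(seq)
        kmers: dict[bytes, list[int]] = defaultdict(list)
        raw = arr.tobytes()
        for j in range(0, len(raw) - k + 1):
            kmers[raw[j : j + k]].append(j)
        refs.append((reference_clades[ref_id], arr, kmers))
    if not refs:
        raise ValueError("reference set is empty")

    rows = []
    for frag in fragments:
        farr = _seq_array(frag.sequence)
        clade_best: dict[str, float] = {}
        for clade, arr, kmers in refs:
            ident = _best_identity(farr, arr, kmers, k=k)
            if ident > clade_best.get(clade, -1.0):
                clade_best[clade] = ident
        top = max(clade_best.values())
        winners = [c for c, v in clade_best.items() if v == top]
        for c in winners:
            rows.append(
                {
                    "read_id": frag.fragment_id,
                    "clade": c,
                    "mass": 1.0 / len(winners),
                    "best_identity": top,
                    "low_identity": top < LOW_IDENTITY,
                }
            )
    return pd.DataFrame(
        rows, columns=["read_id", "clade", "mass", "best_identity", "low_identity"]
    )


def confusion_summary(
    placements: pd.DataFrame,
    truth: Mapping[str, str],
    target_clades: Sequence[str],
    gene_family: str = "gene",
) -> list[ValidationSummary]:
    """Sensitivity and specificity per target clade.

    A fragment's call is the clade holding its largest placement mass.
    Sensitivity for a clade is the fraction of fragments truly from that
    clade called into it. Specificity is one minus the fraction of
    outgroup fragments called into any ingroup clade; for multi-clade
    families a call into any non-target ingroup clade equally counts
    against the target clade, so the outgroup-leakage denominator is
    shared across clades.
    """
    calls: dict[str, str] = {}
    for read_id, sub in placements.groupby("read_id", sort=False):
        calls[read_id] = sub.set_index("clade")["mass"].idxmax()
    missing = [r for r in calls if r not in truth]
    if missing:
        raise ValueError(f"placements without truth labels: {missing[:5]}")

    ingroup = set(target_clades)
    out_total = sum(1 for r, lab in truth.items() if lab == "outgroup" and r in calls)
    out_in_ingroup = sum(
        1
        for r, call in calls.items()
        if truth[r] == "outgroup" and call in ingroup
    )
    specificity = 1.0 - (out_in_ingroup / out_total if out_total else 0.0)

    summaries = []
    for clade in target_clades:
        members = [r for r in calls if truth[r] == clade]
        hit = sum(1 for r in members if calls[r] == clade)
        summaries.append(
            ValidationSummary(
                gene_family=gene_family,
                clade=clade,
                sensitivity=hit / len(members) if members else float("nan"),
                specificity=specificity,
                n_ingroup=len(members),
                n_outgroup=out_total,
            )
        )
    return summaries
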