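"""Sub-genome read tagging against two diploid-progenitor transcript panels.

Each read is scored against an A-like and a D-like panel with a seeded,
ungapped local aligner (score = matches - mismatches, 11-mer seeds), and
assigned the tag of the strictly better panel when both panels are hit above
a minimum score. Equal best scores, or similarity with only one panel, leave
the read untagged (``unknown``); a permissive switch assigns one-sided hits
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._dna import encode, revcomp
from .aio import LIBRARIES, TaggedRead, read_fasta


@dataclass
class ProgenitorPanel:
    """A labelled progenitor-like transcript panel with a k-mer seed index."""

    label: str  # "A" or "D"
    sequences: list[tuple[str, str]]  # (id, sequence)
    _codes: list[np.ndarray] = field(default_factory=list, repr=False)
    _index: dict[str, list[tuple[int, int]]] | None = field(default=None, repr=False)
    _index_k: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.label not in ("A", "D"):
            raise ValueError("panel label must be 'A' or 'D'")
        if not self.sequences:
            raise ValueError("panel must contain at least one sequence")

    @classmethod
    def from_fasta(cls, path: str | Path, label: str) -> "ProgenitorPanel":
        return cls(label, [(r.id, str(r.seq)) for r in read_fasta(path)])

    def codes(self) -> list[np.ndarray]:
        if not self._codes:
            self._codes = [encode(s) for _, s in self.sequences]
        return self._codes

    def seed_index(self, k: int) -> dict[str, list[tuple[int, int]]]:
        """Non-overlapping k-mers of each panel sequence -> (seq index, offset)."""
        if self._index is None or self._index_k != k:
            index: dict[str, list[tuple[int, int]]] = {}
            for si, (_, seq) in enumerate(self.sequences):
                for off in range(0, len(seq) - k + 1, k):
                    kmer = seq[off : off + k]
                    if "N" in kmer:
                        continue
                    index.setdefault(kmer, []).append((si, off))
            self._index = index
            self._index_k = k
        return self._index


@dataclass
class TagDecision:
    read_id: str
    score_a: int
    score_d: int
    tag: str  # A | D | unknown
    reason: str  # a_better | d_better | tie | single_hit | no_hit


def _best_diagonal_score(read: np.ndarray, target: np.ndarray, diag: int) -> int:
    """Best ungapped local score (+1 match, -1 mismatch) on one diagonal."""
    lo = max(0, -diag)
    hi = min(len(read), len(target) - diag)
    if hi <= lo:
        return 0
    v = np.where(read[lo:hi] == target[lo + diag : hi + diag], 1, -1)
    # Kadane via prefix sums: max over j of prefix[j] - min(prefix[i<j])
    prefix = np.concatenate(([0], np.cumsum(v)))
    return int(np.max(prefix[1:] - np.minimum.accumulate(prefix[:-1])))


def similarity_score(read: str, panel: ProgenitorPanel, k: int = 11) -> int:
    """Best-hit score of a read against a panel (0 when no seed matches).

    Both the read and its reverse complement are searched; seed hits on a
    common diagonal are extended ungapped, and the best matches-minus-
    mismatches segment over all seeded diagonals is returned.
    """
    if len(read) < k:
        return 0
    index = panel.seed_index(k)
    codes = panel.codes()
    best = 0
    for query in (read, revcomp(read)):
        qcodes = encode(query)
        seen: set[tuple[int, int]] = set()
        for i in range(len(query) - k + 1):
            for si, off in index.get(query[i : i + k], ()):
                key = (si, off - i)
                if key in seen:
                    continue
                seen.add(key)
                best = max(best, _best_diagonal_score(qcodes, codes[si], off - i))
    return best


def tag_read(
    read: TaggedRead | str,
    panel_a: ProgenitorPanel,
    panel_d: ProgenitorPanel,
    min_score: int = 30,
    k: int = 11,
    assign_single_hits: bool = False,
) -> TagDecision:
    """Assign A/D/unknown from the two panel scores.

    Both scores at or above `min_score` and strictly unequal give the tag of
    the better panel; equal scores are a tie; a hit against only one panel is
    labelled unknown (``single_hit``) unless `assign_single_hits` is set.
    """
    rid = read.id if isinstance(read, TaggedRead) else "read"
    seq = read.sequence if isinstance(read, TaggedRead) else read
    sa = similarity_score(seq, panel_a, k)
    sd = similarity_score(seq, panel_d, k)
    a_ok, d_ok = sa >= min_score, sd >= min_score
    if a_ok and d_ok:
        if sa > sd:
            return TagDecision(rid, sa, sd, "A", "a_better")
        if sd > sa:
            return TagDecision(rid, sa, sd, "D", "d_better")
        return TagDecision(rid, sa, sd, "unknown", "tie")
    if a_ok or d_ok:
        if assign_single_hits:
            return TagDecision(rid, sa, sd, "A" if a_ok else "D", "single_hit")
        return TagDecision(rid, sa, sd, "unknown", "single_hit")
    return TagDecision(rid, sa, sd, "unknown", "no_hit")


def tag_library(
    reads: Sequence[TaggedRead],
    panel_a: ProgenitorPanel,
    panel_d: ProgenitorPanel,
    min_score: int = 30,
    k: int = 11,
    assign_single_hits: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag every read; return the decision table and a per-library summary."""
    rows = []
    for r in reads:
        d = tag_read(r, panel_a, panel_d, min_score, k, assign_single_hits)
        rows.append((d.read_id, r.library, d.score_a, d.score_d, d.tag, d.reason))
    decisions = pd.DataFrame(
        rows, columns=["read_id", "library", "score_a", "score_d", "tag", "reason"]
    )
    if decisions.empty:
        summary = pd.DataFrame(
            0, index=list(LIBRARIES), columns=["A", "D", "unknown", "tagged_fraction"]
        )
        return decisions, summary
    counts = (
        decisions.pivot_table(index="library", columns="tag", values="read_id",
                              aggfunc="count", fill_value=0)
        .reindex(index=list(LIBRARIES), columns=["A", "D", "unknown"], fill_value=0)
    )
    totals = counts.sum(axis=1)
    counts["tagged_fraction"] = ((counts["A"] + counts["D"]) / totals.replace(0, np.nan)).fillna(0.0)
    return decisions, counts


def apply_tags(reads: Iterable[TaggedRead], decisions: pd.DataFrame) -> dict[str, str]:
    """Write decisions back onto reads; return a read id -> tag map."""
    tags = dict(zip(decisions["read_id"], decisions["tag"]))
    for r in reads:
        r.tag = tags.get(r.id, "unknown")
    return tags
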