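"""Quartet alignment preparation.

Alignments enter the analysis already built (externally, or synthetic);
this module implements the coverage pruning applied per quartet before
branch-length estimation: a codon (coding data) or site (non-coding data)
is kept only if at least one tip in each sister clade *and* in the
outgroup has data there, where "data" means an unambiguous A/C/G/T.
Quartets retaining 100 or fewer bases are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = frozenset("ACGTacgt")

MIN_BASES = 100  # a quartet keeping <= this many bases is dropped


@dataclass
class Alignment:
    """A multiple-sequence alignment with an optional partition structure.

    ``partitions`` is a list of (start, end, frame) half-open column
    ranges with frame "coding" or "noncoding"; when omitted the whole
    alignment takes ``frame``.  Coding partitions must have length
    divisible by 3.
    """

    sequences: dict[str, str]
    frame: str = "coding"
    partitions: list[tuple[int, int, str]] | None = None

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        if self.frame not in ("coding", "noncoding"):
            raise ValueError("frame must be 'coding' or 'noncoding'")
        if self.partitions is None:
            self.partitions = [(0, self.length, self.frame)]
        pos = 0
        for start, end, frame in self.partitions:
            if start != pos or end <= start:
                raise ValueError("partitions must tile the alignment")
            if frame == "coding" and (end - start) % 3:
                raise ValueError("coding partition length not divisible by 3")
            pos = end
        if pos != self.length:
            raise ValueError("partitions do not cover the alignment")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @classmethod
    def from_fasta(cls, path, frame: str = "coding", partitions=None):
        seqs = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
        }
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(seqs, frame=frame, partitions=partitions)

    def to_fasta(self, path):
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")


def _has_data(seq: str, start: int, width: int) -> bool:
    chunk = seq[start:start + width]
    return all(c in _UNAMBIGUOUS for c in chunk)


def prune_alignment(
    aln: Alignment,
    quartet,
    min_bases: int = MIN_BASES,
) -> Alignment | None:
    """Apply the three-way coverage rule per codon/site.

    A column unit (codon for coding partitions, single site otherwise) is
    retained iff it carries an unambiguous base for at least one tip of
    the focal pair's clade A, one of clade B and one of the outgroup
    pair's tips.  Returns the pruned alignment, or None if ``min_bases``
    or fewer bases survive (the quartet is dropped).
    """
    focal = quartet.focal_pair
    groups = (
        set(focal.balanced_a or focal.clade_a_tips),
        set(focal.balanced_b or focal.clade_b_tips),
        set(quartet.outgroup_pair.balanced_a
            or quartet.outgroup_pair.clade_a_tips)
        | set(quartet.outgroup_pair.balanced_b
              or quartet.outgroup_pair.clade_b_tips),
    )
    for grp in groups:
        missing = {t for t in grp if t not in aln.sequences}
        if missing:
            raise KeyError(
                f"quartet tips absent from alignment: {sorted(missing)}"
            )
    keep_cols: list[tuple[int, int]] = []   # (start, width) units kept
    new_partitions = []
    new_pos = 0
    for start, end, frame in aln.partitions:
        width = 3 if frame == "coding" else 1
        kept_here = 0
        for col in range(start, end, width):
            ok = all(
                any(_has_data(aln.sequences[t], col, width) for t in grp)
                for grp in groups
            )
            if ok:
                keep_cols.append((col, width))
                kept_here += width
        if kept_here:
            new_partitions.append((new_pos, new_pos + kept_here, frame))
            new_pos += kept_here
    n_bases = sum(w for _, w in keep_cols)
    if n_bases <= min_bases:
        logger.info(
            "%s dropped: %d bases retained (<= %d)",
            focal.pair_id, n_bases, min_bases,
        )
        return None
    tips = set().union(*groups)
    pruned = {
        name: "".join(seq[c:c + w] for c, w in keep_cols)
        for name, seq in aln.sequences.items()
        if name in tips
    }
    return Alignment(pruned, frame=aln.frame, partitions=new_partitions or None)
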