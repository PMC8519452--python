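"""Amplicon-sequencing readout of the drive target site.

Reads are globally aligned to the amplicon reference, filtered on mean
base quality, and classified: a read is *modified* if the alignment shows
a mismatch, deletion or insertion within one base either side of the
predicted Cas9 cut (the blunt cut 3 bp 5' of the PAM), and *frameshift*
if its net indel length is not a multiple of three.  The per-allele tally
and the two marginals (fraction of alleles modified; fraction of modified
alleles that are in-frame) summarise the resistance spectrum of a pooled
sample.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

GAP = "-"
_ALPHABET = "ACGTN"

#: gRNA protospacer of the drive target and its PAM.
CANONICAL_PROTOSPACER = "GAACAACAACAAAAGACTGT"
CANONICAL_PAM = "AGG"
CANONICAL_LENGTH = 349
CANONICAL_PROTOSPACER_START = 163

#: alignment scoring: match +2, mismatch -1, gap open -5 (first gapped
#: base), gap extend -1 (each further base).  N never matches anything.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2.0, -1.0, -5.0, -1.0


def _substitution_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = MATCH if (a == b and a != "N") else MISMATCH
    return m


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix()
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AmpliconReference:
    """Amplicon reference with target-site annotations.

    ``cut_index`` is the 0-based boundary coordinate of the blunt cut,
    between protospacer bases 17 and 18, i.e. 3 bp 5' of the PAM.
    ``coding_frame_offset`` gives the reading frame of the first base.
    """

    sequence: str
    protospacer_start: int
    coding_frame_offset: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        ps = self.protospacer
        if len(ps) != 20:
            raise ValueError("protospacer must be 20 nt inside the reference")
        pam = self.pam
        if len(pam) != 3 or pam[1:] != "GG":
            raise ValueError(f"PAM {pam!r} does not match NGG")
        if self.coding_frame_offset not in (0, 1, 2):
            raise ValueError("coding_frame_offset must be 0, 1 or 2")

    @property
    def protospacer(self) -> str:
        return self.sequence[self.protospacer_start:self.protospacer_start + 20]

    @property
    def pam(self) -> str:
        return self.sequence[self.protospacer_start + 20:self.protospacer_start + 23]

    @property
    def cut_index(self) -> int:
        return self.protospacer_start + 17

    @staticmethod
    def canonical() -> "AmpliconReference":
        """The 349-bp fixture reference.

        The true genomic amplicon is not reproduced here; the fixture embeds
        the drive's protospacer (GAACAACAACAAAAGACTGT) and AGG PAM at a fixed
        offset inside synthetic flanks (seeded random sequence).
        """
        rng = np.random.default_rng(29113)
        core = CANONICAL_PROTOSPACER + CANONICAL_PAM
        n_left = CANONICAL_PROTOSPACER_START
        n_right = CANONICAL_LENGTH - n_left - len(core)
        bases = np.array(list("ACGT"))
        left = "".join(rng.choice(bases, size=n_left))
        right = "".join(rng.choice(bases, size=n_right))
        seq = left + core + right
        assert seq.count(CANONICAL_PROTOSPACER) == 1
        return AmpliconReference(seq, n_left)

    def with_flanks(self, left: str, right: str) -> "AmpliconReference":
        """Padded copy; the cut site and downstream calls must not change."""
        pad = len(left)
        return AmpliconReference(
            left + self.sequence + right,
            self.protospacer_start + pad,
            (self.coding_frame_offset - pad) % 3,
        )


# ---------------------------------------------------------------------------
# edited-allele constructors (used by the read simulator and tests)

def deletion_allele(ref: AmpliconReference, length: int) -> str:
    """Reference with ``length`` bases deleted ending at the cut."""
    if length < 1:
        raise ValueError("deletion length must be >= 1")
    cut = ref.cut_index
    return ref.sequence[:cut - length] + ref.sequence[cut:]


def insertion_allele(ref: AmpliconReference, bases: str) -> str:
    """Reference with ``bases`` inserted at the cut."""
    if not bases:
        raise ValueError("insertion must be non-empty")
    cut = ref.cut_index
    return ref.sequence[:cut] + bases.upper() + ref.sequence[cut:]


def substitution_allele(ref: AmpliconReference, offset: int = 0,
                        base: Optional[str] = None) -> str:
    """Reference with one substituted base at ``cut_index + offset``.

    By default substitutes to the next base in ACGT order, guaranteeing a
    mismatch.
    """
    pos = ref.cut_index + offset
    if not 0 <= pos < len(ref.sequence):
        raise ValueError("substitution falls outside the reference")
    old = ref.sequence[pos]
    if base is None:
        base = "ACGT"[("ACGT".index(old) + 1) % 4]
    if base == old:
        raise ValueError(f"substitution to the same base {base!r}")
    return ref.sequence[:pos] + base + ref.sequence[pos + 1:]


# ---------------------------------------------------------------------------
# alignment

@dataclass(frozen=True)
class Alignment:
    """Global alignment of a read against the reference, with gap symbols."""

    ref_row: str
    read_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.read_row):
            raise ValueError("aligned rows differ in length")


def _validate_nt(read: str) -> str:
    read = read.upper()
    bad = set(read) - set(_ALPHABET)
    if bad:
        raise ValueError(f"non-nucleotide characters in read: {sorted(bad)}")
    if not read:
        raise ValueError("empty read")
    return read


def align_pair(ref_seq: str, read: str) -> Alignment:
    """Globally align two raw nucleotide strings under the fixed scheme."""
    read = _validate_nt(read)
    best = _ALIGNER.align(ref_seq.upper(), read)[0]
    return Alignment(ref_row=str(best[0]), read_row=str(best[1]),
                     score=float(best.score))


def global_align(read: str, reference: AmpliconReference) -> Alignment:
    """Optimal global alignment under the fixed affine scoring scheme.

    Ties are broken deterministically (the aligner's canonical first
    traceback), so repeated calls give identical alignments.
    """
    return align_pair(reference.sequence, read)


# ---------------------------------------------------------------------------
# quality filter

def mean_quality_filter(read: str, quality: str, min_mean_q: float = 30.0) -> bool:
    """Keep a read iff its mean Phred score (Phred+33) is >= the threshold."""
    if len(read) != len(quality):
        raise ValueError(
            f"quality string length {len(quality)} != read length {len(read)}"
        )
    phred = np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(float) - 33.0
    return bool(phred.mean() >= min_mean_q)


# ---------------------------------------------------------------------------
# classification

@dataclass(frozen=True)
class AlleleCall:
    """Classification of one aligned read.

    ``net_indel`` is inserted minus deleted bases over the read's aligned
    span (leading/trailing read gaps excluded).  ``frameshift`` is true iff
    the read is modified and net_indel is not a multiple of 3 — unmodified
    reads are never frameshift calls.
    """

    modified: bool
    net_indel: int
    frameshift: bool
    event_description: str
    informative: bool = True


def classify_read(alignment: Alignment, reference: AmpliconReference,
                  window: int = 1) -> AlleleCall:
    """Apply the cut-site window rule to one alignment.

    Modified iff the alignment contains, on reference coordinates, a
    mismatch or deletion at a position in [cut-window, cut+window], or an
    insertion anchored within the window boundaries (exactly at the cut for
    window=1).  Alignments whose read span does not cover the window are
    flagged uninformative and excluded from tallies.
    """
    cut = reference.cut_index
    win_lo, win_hi = cut - window, cut + window  # inclusive position range

    ref_row, read_row = alignment.ref_row, alignment.read_row
    cols = len(ref_row)
    # read aligned span: columns between the first and last read base
    read_cols = [i for i in range(cols) if read_row[i] != GAP]
    if not read_cols:
        return AlleleCall(False, 0, False, "empty", informative=False)
    lo_col, hi_col = read_cols[0], read_cols[-1]

    modified = False
    inserted = deleted = 0
    events: List[str] = []
    span_start = span_end = None  # reference coords covered by the read span
    r = 0  # reference coordinate (bases consumed)
    i = 0
    while i < cols:
        a, b = ref_row[i], read_row[i]
        in_span = lo_col <= i <= hi_col
        if a != GAP and b != GAP:
            if in_span:
                span_start = r if span_start is None else span_start
                span_end = r + 1
                if a != b and win_lo <= r <= win_hi:
                    modified = True
                if a != b:
                    events.append(f"sub@{r - cut:+d}")
            r += 1
            i += 1
        elif b == GAP:  # deletion in the read
            if in_span:
                span_start = r if span_start is None else span_start
                span_end = r + 1
                deleted += 1
                if win_lo <= r <= win_hi:
                    modified = True
                events.append(f"del@{r - cut:+d}")
            r += 1
            i += 1
        else:  # a == GAP: insertion in the read, anchored at boundary r
            run = 0
            while i < cols and ref_row[i] == GAP:
                if lo_col <= i <= hi_col:
                    run += 1
                i += 1
            if run:
                inserted += run
                if abs(r - cut) < max(window, 1):
                    modified = True
                events.append(f"ins:+{run}@{r - cut:+d}")

    covers = (
        span_start is not None
        and span_start <= win_lo
        and span_end is not None
        and span_end >= win_hi + 1
    )
    net = inserted - deleted
    description = ";".join(events) if events else "ref"
    if not covers:
        return AlleleCall(False, net, False, description, informative=False)
    frameshift = modified and (net % 3 != 0)
    return AlleleCall(modified, net, frameshift, description)


# ---------------------------------------------------------------------------
# tallies

@dataclass
class AlleleSpectrum:
    """Per-allele tallies plus the two modification marginals."""

    table: pd.DataFrame  # columns: allele, count, frequency, modified, frameshift
    n_reads: int
    fraction_modified: float
    in_frame_among_modified: float  # NaN when nothing is modified

    def frequency_of(self, allele: str) -> float:
        hit = self.table.loc[self.table["allele"] == allele, "frequency"]
        return float(hit.iloc[0]) if len(hit) else 0.0


def tally_spectrum(calls: Sequence[AlleleCall], alleles: Sequence[str]) -> AlleleSpectrum:
    """Aggregate informative calls into an allele spectrum.

    ``alleles`` are the allele strings (read sequences) matching ``calls``
    one-to-one; uninformative calls are dropped before tallying.
    """
    if len(calls) != len(alleles):
        raise ValueError("calls and alleles differ in length")
    kept = [(c, a) for c, a in zip(calls, alleles) if c.informative]
    if not kept:
        raise ValueError("no informative reads: every alignment missed the "
                         "quantification window")
    n = len(kept)
    counts: Counter = Counter(a for _, a in kept)
    call_by_allele: Dict[str, AlleleCall] = {}
    for c, a in kept:
        call_by_allele.setdefault(a, c)
    rows = [
        (a, cnt, cnt / n, call_by_allele[a].modified, call_by_allele[a].frameshift)
        for a, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    table = pd.DataFrame(rows, columns=["allele", "count", "frequency",
                                        "modified", "frameshift"])
    n_modified = sum(1 for c, _ in kept if c.modified)
    fraction_modified = n_modified / n
    if n_modified:
        in_frame = sum(1 for c, _ in kept if c.modified and not c.frameshift)
        in_frame_among_modified = in_frame / n_modified
    else:
        in_frame_among_modified = float("nan")
    return AlleleSpectrum(table, n, fraction_modified, in_frame_among_modified)


# ---------------------------------------------------------------------------
# pipeline entry points

def read_reference_fasta(path: str) -> AmpliconReference:
    """Load an annotated reference: one FASTA record, protospacer located
    by exact match to the canonical gRNA spacer."""
    record = next(SeqIO.parse(path, "fasta"))
    seq = str(record.seq).upper()
    start = seq.find(CANONICAL_PROTOSPACER)
    if start < 0:
        raise ValueError("reference does not contain the drive protospacer")
    return AmpliconReference(seq, start)


def classify_fastq(
    reads_path: str,
    reference: AmpliconReference,
    min_mean_q: float = 30.0,
    window: int = 1,
) -> Tuple[AlleleSpectrum, Dict[str, int]]:
    """Full readout: quality filter, align, classify, tally.

    Returns the spectrum and a counter of reads discarded at each stage.
    """
    calls: List[AlleleCall] = []
    alleles: List[str] = []
    discarded = {"quality": 0, "uninformative": 0, "total": 0}
    cache: Dict[str, AlleleCall] = {}  # identical reads get identical calls
    for record in SeqIO.parse(reads_path, "fastq"):
        discarded["total"] += 1
        seq = str(record.seq).upper()
        qual = "".join(chr(q + 33) for q in record.letter_annotations["phred_quality"])
        if not mean_quality_filter(seq, qual, min_mean_q):
            discarded["quality"] += 1
            continue
        call = cache.get(seq)
        if call is None:
            call = classify_read(global_align(seq, reference), reference, window)
            cache[seq] = call
        if not call.informative:
            discarded["uninformative"] += 1
            continue
        calls.append(call)
        alleles.append(seq)
    if not calls:
        raise ValueError("no reads survived filtering")
    spectrum = tally_spectrum(calls, alleles)
    discarded["kept"] = len(calls)
    return spectrum, discarded


def write_reference_fasta(reference: AmpliconReference, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(">amplicon_reference synthetic fixture\n")
        seq = reference.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
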