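"""Dataset construction for splice-site classification.

From genes (sequence + exon map) this module extracts fixed-length windows
centered on splice sites (positives), samples three categories of negative
windows (false-positive GT/AG occurrences, exon background, intron
background), assembles them under named composition strategies (quality
tier x negative mix x class ratio), performs a stratified train/test split,
and computes dataset QC statistics: pairwise percent identity
distributions, canonical-site counts and position frequency matrices.

Conventions
-----------
Coordinates are 1-based inclusive on the forward strand.  A window of even
length L carries its central dinucleotide at positions L/2 and L/2+1
(1-based); for a donor window that dinucleotide is the first two intron
bases (canonically GT), for an acceptor window the last two (canonically
AG).  ``center_pos`` is the genomic coordinate of the first base of the
central dinucleotide.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GeneRecord

logger = logging.getLogger(__name__)

SITE_TYPES = ("donor", "acceptor")
ORIGINS = ("true_site", "fp_dinucleotide", "exon_bg", "intron_bg")
CANONICAL_DINUCLEOTIDE = {"donor": "GT", "acceptor": "AG"}

#: Named composition strategies: (quality tier, ratio, negative mix).
#: "GS" uses confirmed genes only; "AS" uses all genes.  The suffix encodes
#: the negative subset: _0 = 1:1 FP-only, _1 = 1:1 heterogeneous,
#: _2 = 1:2 FP-only, _10 = 1:10 FP-only.
STRATEGIES: dict[str, tuple[str, int, str]] = {
    "AS_0": ("all", 1, "fp_only"),
    "AS_1": ("all", 1, "heterogeneous"),
    "AS_2": ("all", 2, "fp_only"),
    "AS_10": ("all", 10, "fp_only"),
    "GS_0": ("confirmed_only", 1, "fp_only"),
    "GS_1": ("confirmed_only", 1, "heterogeneous"),
    "GS_2": ("confirmed_only", 2, "fp_only"),
    "GS_10": ("confirmed_only", 10, "fp_only"),
}

#: Exon/intron negative counts are quantized down to multiples of this many
#: sequences (when large enough), the remainder going to the FP category —
#: reproducing the 3650/3650/3700 pattern used for 11,000 heterogeneous
#: negatives and 4000/4000/4000 for 12,000.
_THIRDS_GRANULARITY = 50


class DatasetError(ValueError):
    pass


class SamplingError(DatasetError):
    """Requested more negative windows than the genes can provide."""


@dataclass(frozen=True)
class SpliceExample:
    """One fixed-length window with its label and provenance."""

    window: str
    label: int                # 1 = splice site, 0 = non-site
    site_type: str            # donor | acceptor
    origin: str               # true_site | fp_dinucleotide | exon_bg | intron_bg
    canonical: bool
    gene_id: str
    center_pos: int           # 1-based genomic coord of first central base

    def __post_init__(self) -> None:
        L = len(self.window)
        if L % 2 or L < 4:
            raise DatasetError(f"window length must be even and >= 4, got {L}")
        if self.site_type not in SITE_TYPES:
            raise DatasetError(f"unknown site_type {self.site_type!r}")
        if self.origin not in ORIGINS:
            raise DatasetError(f"unknown origin {self.origin!r}")
        if (self.label == 1) != (self.origin == "true_site"):
            raise DatasetError("label=1 iff origin=true_site")

    @property
    def central_dinucleotide(self) -> str:
        L = len(self.window)
        return self.window[L // 2 - 1: L // 2 + 1]


@dataclass(frozen=True)
class DatasetSpec:
    """One dataset composition strategy.

    ``ratio`` is the negative:positive multiplier (1, 2 or 10 in the named
    strategies).  ``replicate`` indexes an independent random negative draw;
    positives are shared across replicates.
    """

    name: str = "GS_1"
    quality: str = "confirmed_only"     # confirmed_only | all
    ratio: int = 1
    negative_mix: str = "heterogeneous"  # fp_only | heterogeneous
    window_length: int = 200
    replicate: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quality not in ("confirmed_only", "all"):
            raise DatasetError(f"unknown quality tier {self.quality!r}")
        if self.negative_mix not in ("fp_only", "heterogeneous"):
            raise DatasetError(f"unknown negative mix {self.negative_mix!r}")
        if self.ratio < 1:
            raise DatasetError("ratio must be a positive integer")
        if self.window_length % 2 or self.window_length < 4:
            raise DatasetError("window_length must be even and >= 4")
        if self.replicate < 1:
            raise DatasetError("replicate index starts at 1")

    @classmethod
    def from_strategy(cls, name: str, window_length: int = 200,
                      replicate: int = 1, seed: int = 0) -> "DatasetSpec":
        if name not in STRATEGIES:
            raise DatasetError(f"unknown strategy {name!r}; choose from {sorted(STRATEGIES)}")
        quality, ratio, mix = STRATEGIES[name]
        return cls(name=name, quality=quality, ratio=ratio, negative_mix=mix,
                   window_length=window_length, replicate=replicate, seed=seed)


@dataclass
class Dataset:
    spec: DatasetSpec
    positives: list[SpliceExample]
    negatives: list[SpliceExample]

    @property
    def examples(self) -> list[SpliceExample]:
        return self.positives + self.negatives

    def to_frame(self) -> pd.DataFrame:
        rows = [(e.window, e.label, e.site_type, e.origin, e.canonical,
                 e.gene_id, e.center_pos) for e in self.examples]
        return pd.DataFrame(rows, columns=["window", "label", "site_type",
                                           "origin", "canonical", "gene_id",
                                           "center_pos"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, spec: DatasetSpec | None = None) -> "Dataset":
        df = pd.read_csv(path, sep="\t")
        examples = [SpliceExample(window=r.window, label=int(r.label),
                                  site_type=r.site_type, origin=r.origin,
                                  canonical=bool(r.canonical), gene_id=r.gene_id,
                                  center_pos=int(r.center_pos))
                    for r in df.itertuples()]
        pos = [e for e in examples if e.label == 1]
        neg = [e for e in examples if e.label == 0]
        if spec is None:
            L = len(examples[0].window) if examples else 200
            spec = DatasetSpec(name="loaded", quality="all", ratio=max(1, len(neg) // max(1, len(pos))),
                               negative_mix="heterogeneous", window_length=L)
        return cls(spec=spec, positives=pos, negatives=neg)


# ---------------------------------------------------------------------------
# Window extraction

def _site_centers(gene: GeneRecord, site_type: str) -> list[int]:
    return gene.donor_sites if site_type == "donor" else gene.acceptor_sites


def _window_at(sequence: str, center: int, flank: int) -> str | None:
    """Window of length 2*flank with the central dinucleotide's first base at
    1-based window position ``flank``; None if out of range or containing N."""
    start = center - flank  # 0-based start index
    end = center + flank    # 0-based exclusive end
    if start < 0 or end > len(sequence):
        return None
    window = sequence[start:end]
    if "N" in window:
        return None
    return window


def extract_positive_windows(genes: Iterable[GeneRecord], site_type: str,
                             flank: int = 300) -> list[SpliceExample]:
    """One window per interior exon boundary of the requested type.

    Windows that would overhang the sequence ends, or contain an undetermined
    base, are discarded.  The canonical flag reflects the central
    dinucleotide (GT for donors, AG for acceptors).  Malformed genes are
    logged and skipped.
    """
    if site_type not in SITE_TYPES:
        raise DatasetError(f"unknown site_type {site_type!r}")
    if flank < 1:
        raise DatasetError("flank must be >= 1")
    canonical_dinuc = CANONICAL_DINUCLEOTIDE[site_type]
    out: list[SpliceExample] = []
    for gene in genes:
        try:
            centers = _site_centers(gene, site_type)
        except Exception as exc:  # malformed exon map
            logger.warning("skipping gene %s: %s", getattr(gene, "gene_id", "?"), exc)
            continue
        for center in centers:
            window = _window_at(gene.sequence, center, flank)
            if window is None:
                continue
            dinuc = window[flank - 1: flank + 1]
            out.append(SpliceExample(window=window, label=1, site_type=site_type,
                                     origin="true_site",
                                     canonical=dinuc == canonical_dinuc,
                                     gene_id=gene.gene_id, center_pos=center))
    return out


def trim_window(example: SpliceExample, L: int) -> SpliceExample:
    """Symmetric crop to length L, keeping the central dinucleotide at
    positions L/2, L/2+1."""
    old = len(example.window)
    if L % 2 or old % 2:
        raise DatasetError("window lengths must be even")
    if L > old:
        raise DatasetError(f"cannot trim {old}-nt window to {L} nt")
    start = old // 2 - L // 2
    return replace(example, window=example.window[start:start + L])


# ---------------------------------------------------------------------------
# Negative sampling

def _annotated_centers(genes: Sequence[GeneRecord], site_type: str) -> set[tuple[str, int]]:
    return {(g.gene_id, c) for g in genes for c in _site_centers(g, site_type)}


def _candidate_centers(gene: GeneRecord, site_type: str, category: str,
                       flank: int, excluded: set[tuple[str, int]]) -> list[int]:
    """Enumerate admissible window centers for one negative category."""
    seq = gene.sequence
    lo, hi = flank, len(seq) - flank  # admissible 0-based index range for center-1
    if category == "fp_dinucleotide":
        dinuc = CANONICAL_DINUCLEOTIDE[site_type]
        candidates = [m.start() + 1 for m in re.finditer(f"(?={dinuc})", seq)]
    elif category in ("exon_bg", "intron_bg"):
        intervals = gene.exons if category == "exon_bg" else gene.introns
        candidates = []
        for start, end in intervals:
            # central dinucleotide (c, c+1) wholly inside the interval
            candidates.extend(range(start, end))
    else:
        raise DatasetError(f"unknown negative category {category!r}")
    # window spans 0-based [c-flank, c+flank): need c >= flank, c+flank <= len
    return [c for c in candidates
            if flank <= c <= len(seq) - flank
            and (gene.gene_id, c) not in excluded]


def sample_negatives(genes: Sequence[GeneRecord], site_type: str, category: str,
                     count: int, exclusion: set[tuple[str, int]],
                     rng: np.random.Generator, flank: int = 300) -> list[SpliceExample]:
    """Sample ``count`` negative windows of one category, without replacement
    on (gene, center) coordinates.

    ``fp_dinucleotide`` centers sit on a GT (donor) or AG (acceptor)
    occurrence that is not an annotated site; ``exon_bg`` / ``intron_bg``
    centers lie wholly inside an exon / intron with no constraint on the
    dinucleotide identity (beyond not being an annotated site).  Windows
    containing N or overhanging the sequence are never candidates.
    """
    if count < 0:
        raise DatasetError("count must be >= 0")
    if count == 0:
        return []
    excluded = set(exclusion) | _annotated_centers(genes, site_type)
    gi_parts, c_parts = [], []
    for gi, gene in enumerate(genes):
        centers = _candidate_centers(gene, site_type, category, flank, excluded)
        if centers:
            gi_parts.append(np.full(len(centers), gi, dtype=np.int64))
            c_parts.append(np.asarray(centers, dtype=np.int64))
    if not gi_parts:
        raise SamplingError(f"no admissible {category} centers (deficit {count})")
    pool_gi = np.concatenate(gi_parts)
    pool_c = np.concatenate(c_parts)
    order = rng.permutation(len(pool_gi))
    canonical_dinuc = CANONICAL_DINUCLEOTIDE[site_type]
    out: list[SpliceExample] = []
    for k in order:
        if len(out) == count:
            break
        gi, c = int(pool_gi[k]), int(pool_c[k])
        gene = genes[gi]
        window = _window_at(gene.sequence, c, flank)
        if window is None:  # N inside; resample by moving on
            continue
        dinuc = window[flank - 1: flank + 1]
        out.append(SpliceExample(window=window, label=0, site_type=site_type,
                                 origin=category, canonical=dinuc == canonical_dinuc,
                                 gene_id=gene.gene_id, center_pos=c))
    if len(out) < count:
        raise SamplingError(
            f"requested {count} {category} negatives but only {len(out)} "
            f"admissible centers exist (deficit {count - len(out)})")
    return out


def deduplicate(examples: Sequence[SpliceExample]) -> list[SpliceExample]:
    """Drop exact window-string duplicates, keeping the first occurrence."""
    seen: set[str] = set()
    out = []
    for e in examples:
        if e.window not in seen:
            seen.add(e.window)
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# Assembly

def _heterogeneous_counts(n: int) -> tuple[int, int, int]:
    """Split n negatives into (intron, exon, FP) counts.

    Intron and exon shares are floor(n/3) quantized down to a multiple of 50
    when large enough; the remainder goes to the FP category.  This yields
    4000/4000/4000 for n=12,000 and 3650/3650/3700 for n=11,000.
    """
    third = n // 3
    if third >= _THIRDS_GRANULARITY:
        third = (third // _THIRDS_GRANULARITY) * _THIRDS_GRANULARITY
    return third, third, n - 2 * third


def assemble_dataset(spec: DatasetSpec, positives: Sequence[SpliceExample],
                     genes: Sequence[GeneRecord], flank: int | None = None,
                     max_redraws: int = 5) -> Dataset:
    """Draw negatives per ``spec`` and enforce the exact class ratio.

    Positives are deduplicated; negatives are drawn (independently per
    replicate index), deduplicated against themselves and the positives,
    topped up if deduplication broke the ratio (bounded redraws), then
    downsampled to exactly ``ratio x |positives|``.
    """
    if not positives:
        raise DatasetError("positives must be non-empty")
    site_type = positives[0].site_type
    if flank is None:
        flank = len(positives[0].window) // 2
    pos = deduplicate(positives)
    n_neg = spec.ratio * len(pos)
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence((spec.seed, spec.replicate))))
    exclusion = {(e.gene_id, e.center_pos) for e in pos}

    if spec.negative_mix == "heterogeneous":
        quotas = dict(zip(("intron_bg", "exon_bg", "fp_dinucleotide"),
                          _heterogeneous_counts(n_neg)))
    else:
        quotas = {"fp_dinucleotide": n_neg}

    seen = {e.window for e in pos}
    negatives: list[SpliceExample] = []
    for category, quota in quotas.items():
        drawn: list[SpliceExample] = []
        want = quota
        for _ in range(max_redraws):
            if want <= 0:
                break
            batch = sample_negatives(genes, site_type, category, want,
                                     exclusion, rng, flank=flank)
            exclusion |= {(e.gene_id, e.center_pos) for e in batch}
            for e in batch:
                if e.window not in seen:
                    seen.add(e.window)
                    drawn.append(e)
            want = quota - len(drawn)
        if want > 0:
            raise SamplingError(
                f"could not assemble {quota} unique {category} negatives "
                f"(short by {want} after {max_redraws} redraws)")
        negatives.extend(drawn[:quota])

    # dedup across categories is already enforced via `seen`; downsample to
    # the exact ratio in case of any surplus
    if len(negatives) > n_neg:
        idx = rng.choice(len(negatives), size=n_neg, replace=False)
        negatives = [negatives[i] for i in sorted(idx)]
    return Dataset(spec=spec, positives=pos, negatives=negatives)


def split_train_test(dataset: Dataset, train_fraction: float = 0.80,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> tuple[Dataset, Dataset]:
    """Shuffled stratified split preserving the class ratio in both parts."""
    if not 0.0 < train_fraction < 1.0:
        raise DatasetError("train_fraction must lie strictly between 0 and 1")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(0 if seed is None else seed))
    train_parts: dict[str, list[SpliceExample]] = {}
    test_parts: dict[str, list[SpliceExample]] = {}
    for name, pool in (("positives", dataset.positives), ("negatives", dataset.negatives)):
        if len(pool) < 5:
            raise DatasetError(f"need at least 5 {name} to split, got {len(pool)}")
        order = rng.permutation(len(pool))
        n_train = int(np.floor(train_fraction * len(pool)))
        train_parts[name] = [pool[i] for i in order[:n_train]]
        test_parts[name] = [pool[i] for i in order[n_train:]]
    train = Dataset(spec=dataset.spec, **train_parts)
    test = Dataset(spec=dataset.spec, **test_parts)
    return train, test


# ---------------------------------------------------------------------------
# QC statistics

@dataclass
class IdentityDistribution:
    """Per-sequence mean pairwise identity, binned into ten 10%-wide bins."""

    bins: np.ndarray          # 10 fractions, [0,10), ..., [90,100]
    n_sequences: int
    mean_of_means: float      # percentage

    def to_frame(self) -> pd.DataFrame:
        labels = [f"[{10*i}-{10*(i+1)}{']' if i == 9 else ')'}%" for i in range(10)]
        return pd.DataFrame({"bin": labels, "fraction": self.bins})


def percent_identity(a: str, b: str) -> float:
    """Ungapped positional identity of two equal-length sequences, in %."""
    if len(a) != len(b):
        raise DatasetError(f"length mismatch: {len(a)} vs {len(b)}")
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a) * 100.0


def identity_distribution(sequences: Sequence[str]) -> IdentityDistribution:
    """Mean pairwise identity per sequence, binned per 10%.

    The top bin [90,100]% is closed so a 100% mean lands in it.
    """
    n = len(sequences)
    if n < 2:
        raise DatasetError("need at least 2 sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise DatasetError("sequences must have equal length")
    # encode to a byte matrix; pairwise identity = mean equality count
    mat = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8).reshape(n, L)
    means = np.empty(n)
    for i in range(n):
        eq = (mat == mat[i]).mean(axis=1) * 100.0
        means[i] = (eq.sum() - 100.0) / (n - 1)  # exclude self
    edges = np.arange(0, 110, 10)
    counts, _ = np.histogram(means, bins=edges)  # numpy: last bin closed
    return IdentityDistribution(bins=counts / n, n_sequences=n,
                                mean_of_means=float(means.mean()))


def position_frequency_matrix(examples: Sequence[SpliceExample | str]) -> pd.DataFrame:
    """Per-position A/C/G/T counts over equal-length windows.

    Returns a DataFrame with one row per position (1-based index) and
    columns A, C, G, T; each row sums to the number of examples (windows
    must be N-free, which dataset construction guarantees).
    """
    windows = [e.window if isinstance(e, SpliceExample) else e for e in examples]
    if not windows:
        raise DatasetError("cannot compute a frequency matrix of nothing")
    L = len(windows[0])
    if any(len(w) != L for w in windows):
        raise DatasetError("windows must have equal length")
    mat = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8).reshape(len(windows), L)
    counts = {base: (mat == ord(base)).sum(axis=0) for base in "ACGT"}
    df = pd.DataFrame(counts, index=pd.RangeIndex(1, L + 1, name="position"))
    return df
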