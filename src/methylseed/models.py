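"""Core domain types shared across the package.

Coordinates are 0-based half-open everywhere inside the package; 1-based
conventions (cytosine reports, GFF3) are converted at the read/write
boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTEXTS = ("CG", "CHG", "CHH")
TE_CLASSES = ("Helitron", "LINE", "LTR", "TIR")
COMPARTMENT_LABELS = ("pericentromeric", "non_pericentromeric")

#: Column order of the canonical cytosine table (one row per strand-specific
#: cytosine).  ``pos`` is 0-based; CX reports on disk are 1-based.
CYTOSINE_COLUMNS = ("chrom", "pos", "strand", "meth", "unmeth", "context", "tricontext")


@dataclass(frozen=True)
class CytosineRecord:
    """A single strand-specific cytosine with its bisulfite call counts."""

    chrom: str
    pos: int  # 0-based
    strand: str
    meth: int
    unmeth: int
    context: str
    tricontext: str = ""

    def __post_init__(self) -> None:
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError("call counts must be non-negative")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.pos < 0:
            raise ValueError("position must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as a strand-aware half-open interval.

    ``start``/``end`` delimit the gene body (UTRs, CDS and introns).  The
    transcription start site is the 5' end in transcription orientation:
    coordinate ``start`` on the + strand, ``end`` on the - strand (both as
    half-open boundaries, so the promoter never includes a body base).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.end - self.start < 1:
            raise ValueError(f"gene {self.gene_id}: empty body interval")
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: negative start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """5' boundary in transcription orientation (half-open convention)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """3' boundary in transcription orientation."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class TEModel:
    """A transposable element interval with one of the four class labels."""

    te_id: str
    chrom: str
    start: int
    end: int
    te_class: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(
                f"TE {self.te_id}: class {self.te_class!r} not in {TE_CLASSES}"
            )
        if self.end - self.start < 1:
            raise ValueError(f"TE {self.te_id}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Compartment:
    """A chromosomal compartment interval (pericentromere vs arm)."""

    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in COMPARTMENT_LABELS:
            raise ValueError(f"unknown compartment label {self.label!r}")
        if self.end - self.start < 1:
            raise ValueError("empty compartment interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MethylationLevel:
    """Call-weighted percent methylation over some set of cytosines.

    ``percent`` is ``100 * meth / total`` when ``total > 0`` and ``None``
    (undefined, never 0%) when no call was evaluated.
    """

    context: str
    meth_calls: int
    total_calls: int

    @property
    def defined(self) -> bool:
        return self.total_calls > 0

    @property
    def percent(self) -> float | None:
        if not self.defined:
            return None
        return 100.0 * self.meth_calls / self.total_calls

    def __add__(self, other: "MethylationLevel") -> "MethylationLevel":
        if other.context != self.context:
            raise ValueError("cannot pool levels of different contexts")
        return MethylationLevel(
            self.context,
            self.meth_calls + other.meth_calls,
            self.total_calls + other.total_calls,
        )


@dataclass
class DMR:
    """A 100-bp promoter window differentially methylated between two samples.

    ``delta`` is ``level_b - level_a`` in percentage points; a DMR requires
    ``abs(delta)`` strictly greater than the calling threshold.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    window_index: int
    context: str
    stage_a: str
    stage_b: str
    level_a: float
    level_b: float

    @property
    def delta(self) -> float:
        return self.level_b - self.level_a


@dataclass
class MetageneProfile:
    """300-bin end-analysis profile: 100 upstream + 100 body + 100 downstream.

    Flank bins are fixed 40-bp tiles; body bins rescale each feature body to
    100 equal parts.  Bins are ordered in transcription orientation, reading
    left to right from 4 kb upstream of the TSS to 4 kb downstream of the TTS.
    """

    context: str
    feature_class: str
    meth: np.ndarray  # (300,) pooled methylated calls per bin
    total: np.ndarray  # (300,) pooled evaluated calls per bin
    n_features: int
    n_skipped: int = 0
    n_bins: int = field(default=100, repr=False)

    @property
    def percent(self) -> np.ndarray:
        """Per-bin percent methylation; NaN where no call was evaluated."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, 100.0 * self.meth / self.total, np.nan)

    @property
    def zones(self) -> np.ndarray:
        n = self.n_bins
        return np.repeat(["up", "body", "down"], n)

    def zone_percent(self, zone: str) -> float:
        """Call-weighted percent over all bins of one zone."""
        mask = self.zones == zone
        tot = int(self.total[mask].sum())
        if tot == 0:
            raise ValueError(f"no evaluated calls in zone {zone!r}")
        return 100.0 * float(self.meth[mask].sum()) / tot
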