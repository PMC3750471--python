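"""Conversion of DNA sequences to cumulated-phase genomic signals.

Each nucleotide is assigned a complex value

    A -> 1 + 1j,   C -> -1 - 1j,   G -> -1 + 1j,   T -> 1 - 1j

whose arguments are pi/4, -3*pi/4, 3*pi/4 and -pi/4 respectively.  The
cumulated phase at position k is the running sum of these angles over the
first k nucleotides, equivalently

    theta_cum[k] = (pi/4) * (3*(n_G - n_C) + (n_A - n_T))

with n_X the count of base X among the first k positions.  The phase is
accumulated *unwrapped* (no modulo 2*pi): it is an unbounded cumulative sum
whose global trend and local shape carry the sequence's composition and
segment structure.

Two independent implementations are provided — the prefix-count formula and
the direct angle accumulation — which must agree to floating precision; the
pair serves as an internal cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Union

import numpy as np

from .errors import EmptyInputError, SequenceValidationError
from .sequence_io import DNASequence

#: Complex value assigned to each nucleotide.
COMPLEX_MAPPING: Dict[str, complex] = {
    "A": 1 + 1j,
    "C": -1 - 1j,
    "G": -1 + 1j,
    "T": 1 - 1j,
}

#: Argument (radians) of each nucleotide's complex value.  'N' contributes a
#: zero angle: the phase is held flat so positional bookkeeping is preserved
#: without biasing the trend toward any base.
PHASE_ANGLES: Dict[str, float] = {
    "A": math.pi / 4,
    "C": -3 * math.pi / 4,
    "G": 3 * math.pi / 4,
    "T": -math.pi / 4,
    "N": 0.0,
}

#: Stages a signal can be in, in pipeline order.
STAGES = ("raw_phase", "filtered", "downsampled", "normalized", "detrended")


@dataclass
class GenomicSignal:
    """A real-valued signal derived from a DNA sequence.

    Parameters
    ----------
    values
        Ordered samples (radians for the raw phase, dimensionless after
        normalization).
    source_id
        Identifier of the originating sequence.
    sample_step
        Original nucleotides per sample (1 before downsampling).
    stage
        One of :data:`STAGES`.
    metadata
        Provenance of applied processing parameters.
    """

    values: np.ndarray
    source_id: str = ""
    sample_step: int = 1
    stage: str = "raw_phase"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise EmptyInputError(
                f"GenomicSignal({self.source_id!r}): values must be a "
                f"non-empty 1-D array"
            )
        if self.sample_step < 1:
            raise ValueError("sample_step must be >= 1")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def __len__(self) -> int:
        return int(self.values.size)

    def derive(self, values: np.ndarray, stage: str, **meta) -> "GenomicSignal":
        """New signal with updated values/stage, inheriting provenance."""
        step = meta.pop("sample_step", self.sample_step)
        md = dict(self.metadata)
        md.update(meta)
        return GenomicSignal(
            values=values,
            source_id=self.source_id,
            sample_step=step,
            stage=stage,
            metadata=md,
        )


def _encoded(seq: DNASequence, strict: bool) -> np.ndarray:
    if len(seq) == 0:
        raise EmptyInputError(f"{seq.id}: cannot transform an empty sequence")
    if strict and "N" in seq.seq:
        pos = seq.seq.index("N") + 1
        raise SequenceValidationError(
            f"{seq.id}: ambiguous base 'N' at position {pos} (strict mode)"
        )
    return np.frombuffer(seq.seq.encode("ascii"), dtype=np.uint8)


def cumulated_phase(seq: DNASequence, strict: bool = False) -> GenomicSignal:
    """Cumulated phase via the prefix-count formula.

    ``values[k] = (pi/4) * (3*(n_G - n_C) + (n_A - n_T))`` with counts taken
    over positions 1..k+1.  One sample per nucleotide.  With ``strict=True``
    any 'N' raises; otherwise 'N' increments no count (angle 0).
    """
    codes = _encoded(seq, strict)
    weights = np.zeros(256, dtype=np.int64)
    weights[ord("A")] = 1
    weights[ord("T")] = -1
    weights[ord("G")] = 3
    weights[ord("C")] = -3
    integer_phase = np.cumsum(weights[codes])
    return GenomicSignal(
        values=(math.pi / 4) * integer_phase,
        source_id=seq.id,
        sample_step=1,
        stage="raw_phase",
        metadata={"transform": "cumulated_phase"},
    )


def cumulated_phase_by_angles(seq: DNASequence, strict: bool = False) -> GenomicSignal:
    """Cumulated phase as the running sum of per-symbol argument angles.

    Reference implementation used to cross-validate :func:`cumulated_phase`;
    the two agree to floating tolerance by construction.
    """
    codes = _encoded(seq, strict)
    angles = np.zeros(256, dtype=np.float64)
    for base, angle in PHASE_ANGLES.items():
        angles[ord(base)] = angle
    return GenomicSignal(
        values=np.cumsum(angles[codes]),
        source_id=seq.id,
        sample_step=1,
        stage="raw_phase",
        metadata={"transform": "cumulated_phase_by_angles"},
    )


def write_signal_txt(signal: GenomicSignal, path: Union[str, Path]) -> None:
    """Export a signal as two-column text: 1-based position, value."""
    positions = np.arange(1, len(signal) + 1) * signal.sample_step
    with open(path, "w") as handle:
        handle.write(f"# source={signal.source_id} stage={signal.stage} "
                     f"sample_step={signal.sample_step}\n")
        for pos, val in zip(positions, signal.values):
            handle.write(f"{pos}\t{val:.12g}\n")


def read_signal_txt(path: Union[str, Path]) -> GenomicSignal:
    """Read a two-column signal file written by :func:`write_signal_txt`."""
    source_id, stage, step = "", "raw_phase", 1
    values = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, val = token.partition("=")
                    if key == "source":
                        source_id = val
                    elif key == "stage":
                        stage = val
                    elif key == "sample_step":
                        step = int(val)
                continue
            values.append(float(line.split()[1]))
    return GenomicSignal(
        values=np.array(values), source_id=source_id, sample_step=step, stage=stage
    )
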