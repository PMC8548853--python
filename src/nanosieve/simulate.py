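"""Seeded squiggle simulator: labelled two-class corpora with pore-model physics.

The generator emulates what a nanopore digitizer records while a DNA
molecule translocates: each k-mer occupying the pore draws a current
level from a k-mer level table, the motor holds it there for a
geometrically distributed dwell (mean = sampling_rate / translocation
speed, about 8.9 samples per base at 4 kHz and 450 bp/s), Gaussian pore
noise rides on top, each read carries its own small gain/offset drift,
and a noisy adapter-like prefix of roughly 1000-1500 samples precedes
the genuine sequence signal.  The trace is quantized to integer DAC
counts with stored channel calibration, so the output is
indistinguishable in structure from FAST5 contents.

Class differences can be injected three ways: different template
sequences (FASTA), GC skew of random templates, or a level shift on a
k-mer subset (k-mers starting with a chosen base), which mimics a
methylation-like systematic perturbation of the current levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nanosieve.errors import ValidationError
from nanosieve.signal_io import Manifest, Squiggle, write_container

__all__ = ["PoreModel", "ClassSpec", "SimConfig", "build_pore_model",
           "random_sequence", "simulate_read", "generate_dataset",
           "mad_units_to_pA"]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

# channel calibration stamped on every simulated read (typical MinION values)
CAL_DIGITISATION = 8192.0
CAL_RANGE_PA = 1500.0
CAL_OFFSET = 10.0


@dataclass
class PoreModel:
    """k-mer -> (mean pA, sd pA) level table."""

    k: int
    means: np.ndarray  # (4^k,) pA
    sds: np.ndarray    # (4^k,) pA
    seed: int

    def __post_init__(self) -> None:
        n = 4 ** self.k
        if self.means.shape != (n,) or self.sds.shape != (n,):
            raise ValidationError(f"level table must cover all {n} {self.k}-mers")
        if np.any(self.sds <= 0):
            raise ValidationError("all level sds must be > 0")


@dataclass
class ClassSpec:
    """How one read class generates template sequences and level perturbations.

    The level shift applies to a stated k-mer subset chosen by
    ``shift_mode``: ``"top"`` selects the ``shifted_fraction`` of k-mers
    with the highest unmodified table levels (the perturbation then
    survives per-read median/MAD normalization, because no probability
    mass crosses the median), while ``"leading_base"`` selects k-mers
    whose first base is in ``shifted_bases`` (a sequence-context
    perturbation that mostly cancels under robust normalization and
    leaves only a distribution-shape signal — a much harder task).
    """

    gc: float = 0.5
    fasta: str | Path | None = None
    level_shift_pA: float = 0.0
    shift_mode: str = "top"
    shifted_fraction: float = 0.25
    shifted_bases: str = "AT"


@dataclass
class SimConfig:
    """Generation parameters; defaults emulate a MinION-like DNA run."""

    classes: list[ClassSpec] = field(default_factory=lambda: [ClassSpec(), ClassSpec()])
    reads_per_class: int = 500
    k: int = 6
    median_bases: float = 700.0      # lognormal read-length median
    length_sigma: float = 0.2        # lognormal shape
    speed_bp_s: float = 450.0
    sampling_rate: float = 4000.0
    noise_sd_pA: float = 2.0         # per-sample pore noise
    fixed_dwell: int | None = None   # constant dwell override (testing)
    adapter_len_range: tuple[int, int] = (1000, 1500)
    adapter_mean_pA: float = 70.0
    adapter_sd_pA: float = 20.0      # high-variance, unlike sequence signal
    scale_jitter: float = 0.05       # per-read gain sd (multiplicative)
    offset_jitter_pA: float = 2.0    # per-read baseline sd
    seed: int = 0

    def validate(self) -> None:
        if len(self.classes) < 2:
            raise ValidationError("at least 2 classes required")
        if min(self.reads_per_class, self.k) < 1:
            raise ValidationError("reads_per_class and k must be >= 1")
        if min(self.median_bases, self.speed_bp_s, self.sampling_rate) <= 0:
            raise ValidationError("lengths, speed and sampling rate must be > 0")
        if self.noise_sd_pA < 0 or self.length_sigma <= 0:
            raise ValidationError("noise sd must be >= 0 and length_sigma > 0")


def build_pore_model(k: int = 6, seed: int = 0) -> PoreModel:
    """Draw a synthetic level table: means in 60-120 pA, sds in 0.5-3 pA."""
    if not 1 <= k <= 8:
        raise ValidationError(f"k must be in 1..8, got {k}")
    rng = np.random.default_rng(seed)
    n = 4 ** k
    means = rng.uniform(60.0, 120.0, size=n)
    sds = rng.uniform(0.5, 3.0, size=n)
    return PoreModel(k=k, means=means, sds=sds, seed=seed)


def mad_units_to_pA(pore_model: PoreModel, delta: float) -> float:
    """Convert a level shift in normalized (signal-MAD) units to picoamperes.

    After per-read MAD normalization the signal scale is dominated by the
    spread of the k-mer level means, so the MAD of the level table is the
    natural conversion factor.
    """
    med = np.median(pore_model.means)
    return float(delta * np.median(np.abs(pore_model.means - med)))


def random_sequence(n_bases: int, gc: float, rng: np.random.Generator) -> str:
    """Random template with the stated GC fraction."""
    if not 0 < gc < 1:
        raise ValidationError(f"gc must be in (0,1), got {gc}")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=n_bases, p=p))


def _encode_kmers(sequence: str, k: int) -> np.ndarray:
    codes = np.fromiter((_CODE[b] for b in sequence), dtype=np.int64,
                        count=len(sequence))
    powers = 4 ** np.arange(k - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return windows @ powers


def shifted_kmer_mask(pore_model: PoreModel, spec: ClassSpec) -> np.ndarray:
    """Boolean mask over the k-mer table: which k-mers get the level shift."""
    if spec.shift_mode == "top":
        if not 0 < spec.shifted_fraction < 1:
            raise ValidationError(
                f"shifted_fraction must be in (0,1), got {spec.shifted_fraction}")
        cutoff = np.quantile(pore_model.means, 1.0 - spec.shifted_fraction)
        return pore_model.means >= cutoff
    if spec.shift_mode == "leading_base":
        n = pore_model.means.size
        first = (np.arange(n) // 4 ** (pore_model.k - 1))
        return np.isin(first, [_CODE[b] for b in spec.shifted_bases])
    raise ValidationError(f"unknown shift_mode {spec.shift_mode!r}")


def simulate_read(pore_model: PoreModel, sequence: str, config: SimConfig,
                  rng: np.random.Generator, *, read_id: str = "read",
                  label: int | None = None, level_shift_pA: float = 0.0,
                  kmer_mask: np.ndarray | None = None) -> Squiggle:
    """Generate one squiggle from a template sequence.

    Deterministic given the rng state.  Levels come from the pore-model
    table (with the class level shift applied to the k-mers selected by
    ``kmer_mask``), dwells are geometric with mean
    sampling_rate/speed (or ``config.fixed_dwell``), Gaussian noise and a
    per-read affine gain/offset are applied, an adapter prefix is
    prepended, and the trace is quantized to DAC counts.
    """
    k = pore_model.k
    if len(sequence) < k:
        raise ValidationError(f"sequence length {len(sequence)} < k={k}")
    kmer_idx = _encode_kmers(sequence, k)
    levels = pore_model.means[kmer_idx].copy()
    if level_shift_pA != 0.0 and kmer_mask is not None:
        levels += level_shift_pA * kmer_mask[kmer_idx]
    levels += rng.normal(0.0, pore_model.sds[kmer_idx])

    if config.fixed_dwell is not None:
        dwells = np.full(levels.size, int(config.fixed_dwell))
    else:
        p = config.speed_bp_s / config.sampling_rate  # mean dwell = 1/p samples
        dwells = rng.geometric(p, size=levels.size)
    signal = np.repeat(levels, dwells)
    if config.noise_sd_pA > 0:
        signal = signal + rng.normal(0.0, config.noise_sd_pA, size=signal.size)

    lo, hi = config.adapter_len_range
    if hi > 0:
        n_adapter = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)
        adapter = rng.normal(config.adapter_mean_pA, config.adapter_sd_pA,
                             size=n_adapter)
        signal = np.concatenate([adapter, signal])

    scale = 1.0 + (rng.normal(0.0, config.scale_jitter) if config.scale_jitter > 0 else 0.0)
    offset_pA = rng.normal(0.0, config.offset_jitter_pA) if config.offset_jitter_pA > 0 else 0.0
    signal = scale * signal + offset_pA

    raw = np.rint(signal * CAL_DIGITISATION / CAL_RANGE_PA - CAL_OFFSET).astype(np.int16)
    return Squiggle(read_id=read_id, raw=raw, offset=CAL_OFFSET,
                    range_pA=CAL_RANGE_PA, digitisation=CAL_DIGITISATION,
                    sampling_rate=config.sampling_rate, label=label)


def _read_fasta_sequences(path: str | Path) -> list[str]:
    seqs, cur = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                    cur = []
            elif line:
                cur.append(line.upper())
    if cur:
        seqs.append("".join(cur))
    if not seqs:
        raise ValidationError(f"no sequences in FASTA {path}")
    return seqs


def generate_dataset(config: SimConfig, out_dir: str | Path,
                     pore_model: PoreModel | None = None
                     ) -> tuple[Path, Manifest]:
    """Generate a labelled corpus: FAST5-style container + TSV manifest.

    One shared pore model (seeded from the config) is used for all
    classes so that only the configured class differences separate them.
    Byte-identical output for identical config.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if pore_model is None:
        pore_model = build_pore_model(config.k, seed=config.seed)

    squiggles: list[Squiggle] = []
    rows = []
    container = out_dir / "reads.fast5"
    masks = [shifted_kmer_mask(pore_model, spec) if spec.level_shift_pA != 0.0
             else None for spec in config.classes]
    for label, spec in enumerate(config.classes):
        templates = _read_fasta_sequences(spec.fasta) if spec.fasta else None
        for i in range(config.reads_per_class):
            n_bases = max(pore_model.k,
                          int(np.rint(rng.lognormal(np.log(config.median_bases),
                                                    config.length_sigma))))
            if templates is not None:
                tpl = templates[int(rng.integers(len(templates)))]
                if len(tpl) > n_bases:
                    start = int(rng.integers(0, len(tpl) - n_bases + 1))
                    seq = tpl[start:start + n_bases]
                else:
                    seq = tpl
            else:
                seq = random_sequence(n_bases, spec.gc, rng)
            read_id = f"sim-c{label}-{i:05d}"
            squiggles.append(simulate_read(
                pore_model, seq, config, rng, read_id=read_id, label=label,
                level_shift_pA=spec.level_shift_pA, kmer_mask=masks[label]))
            rows.append((read_id, label, container.name))

    write_container(squiggles, container)
    manifest = Manifest(pd.DataFrame(rows, columns=["read_id", "label", "source_file"]))
    manifest.to_tsv(out_dir / "manifest.tsv")
    return container, manifest
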