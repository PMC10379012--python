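"""Synthetic labeled promoter/non-promoter window generator.

Positives emulate TATA-containing promoter windows: i.i.d. background at a
configurable GC content with the TATA-box consensus (default ``TATAAA``)
planted 25-35 bp upstream of the TSS in a configurable fraction of
sequences.  Negatives emulate exon/intron sequence: a low-order Markov
background at a (typically lower) GC content with no planted motif.  The
generator exists to exercise the pipeline end to end without any external
dataset; it does not claim biological realism (no CpG islands, Inr or
CAAT elements).

Every run is fully determined by its seed and emits a ground-truth
manifest of planted motif positions, so recovery tests never re-derive
truth by scanning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import PromoterDataset, SequenceRecord, write_fasta

BASES = "ACGT"


@dataclass
class SyntheticConfig:
    """Study conditions for one generated dataset.

    The default 300-bp window with ``tss_index`` 249 matches the [-249, +50]
    convention; the motif offset is measured upstream from the TSS, so a
    planted motif starts in window positions [tss_index-35, tss_index-25].
    """

    n_pos: int = 200
    n_neg: int = 200
    window_length: int = 300
    tss_index: int = 249
    tata_fraction: float = 1.0
    motif: str = "TATAAA"
    motif_offset_range: tuple[int, int] = (25, 35)
    pos_gc: float = 0.55
    neg_gc: float = 0.45
    neg_order: int = 1
    neg_persistence: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not 0 <= self.tata_fraction <= 1:
            raise ValueError("tata_fraction must be in [0, 1]")
        for gc in (self.pos_gc, self.neg_gc):
            if not 0 < gc < 1:
                raise ValueError("GC content must be in (0, 1)")
        lo, hi = self.motif_offset_range
        if lo > hi or lo < 0:
            raise ValueError("invalid motif_offset_range")
        if self.tss_index - hi < 0 or self.tss_index - lo + len(self.motif) > self.window_length:
            raise ValueError("motif does not fit inside the window at every offset")
        if self.neg_order not in (0, 1):
            raise ValueError("neg_order must be 0 or 1")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _iid_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=length, p=_base_probs(gc))
    return "".join(BASES[i] for i in idx)


def _markov_sequence(
    length: int, gc: float, persistence: float, rng: np.random.Generator
) -> str:
    """Order-1 chain: P(b|a) = (1-rho)*pi_b + rho*[b==a]; stationary dist pi."""
    pi = _base_probs(gc)
    trans = (1 - persistence) * np.tile(pi, (4, 1)) + persistence * np.eye(4)
    idx = np.empty(length, dtype=int)
    idx[0] = rng.choice(4, p=pi)
    for i in range(1, length):
        idx[i] = rng.choice(4, p=trans[idx[i - 1]])
    return "".join(BASES[i] for i in idx)


def sample_promoter(
    config: SyntheticConfig, rng: np.random.Generator, identifier: str = "pos"
) -> tuple[SequenceRecord, int | None]:
    """One positive window; returns (record, planted motif start or None)."""
    seq = list(_iid_sequence(config.window_length, config.pos_gc, rng))
    motif_start: int | None = None
    if rng.random() < config.tata_fraction:
        lo, hi = config.motif_offset_range
        offset = int(rng.integers(lo, hi + 1))
        motif_start = config.tss_index - offset
        seq[motif_start : motif_start + len(config.motif)] = config.motif
    return SequenceRecord(identifier, "".join(seq), 1), motif_start


def sample_non_promoter(
    config: SyntheticConfig, rng: np.random.Generator, identifier: str = "neg"
) -> SequenceRecord:
    """One negative window with Markov background and no planted motif."""
    if config.neg_order == 0:
        seq = _iid_sequence(config.window_length, config.neg_gc, rng)
    else:
        seq = _markov_sequence(
            config.window_length, config.neg_gc, config.neg_persistence, rng
        )
    return SequenceRecord(identifier, seq, 0)


@dataclass
class GroundTruth:
    """Generator manifest: config echo and planted motif positions by id."""

    config: SyntheticConfig
    motif_positions: dict[str, int | None] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {"config": asdict(self.config), "motif_positions": self.motif_positions}
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_dataset(config: SyntheticConfig) -> tuple[PromoterDataset, GroundTruth]:
    """n_pos positives + n_neg negatives, seeded and shuffled."""
    if config.n_pos < 1 or config.n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(config=config)
    records: list[SequenceRecord] = []
    for i in range(config.n_pos):
        rec, pos = sample_promoter(config, rng, f"pos_{i:05d}")
        truth.motif_positions[rec.identifier] = pos
        records.append(rec)
    for i in range(config.n_neg):
        records.append(sample_non_promoter(config, rng, f"neg_{i:05d}"))
    order = rng.permutation(len(records))
    dataset = PromoterDataset(
        [records[i] for i in order], config.window_length, config.tss_index
    )
    return dataset, truth


def write_dataset(
    dataset: PromoterDataset, truth: GroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Emit positives/negatives FASTA plus the JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "positives": out / "positives.fasta",
        "negatives": out / "negatives.fasta",
        "manifest": out / "manifest.json",
    }
    write_fasta([r for r in dataset.records if r.label == 1], paths["positives"])
    write_fasta([r for r in dataset.records if r.label == 0], paths["negatives"])
    truth.to_json(paths["manifest"])
    return paths
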