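"""Per-nucleotide local feature encodings.

Four encodings are provided, all strictly positional over the A/C/G/T
alphabet:

* **NCP** (nucleotide chemical property) — three binary indicators per
  base: ring structure r (purine=1), hydrogen-bond strength h (weak
  A/T=1), functional group f (amino A/C=1).
* **ND** (nucleotide density) — the prefix frequency of the current base:
  component i is (occurrences of base i among positions 1..i) / i.
* **EIIP** — the electron–ion interaction pseudopotential energy of each
  base, a fixed scalar lookup.
* **BPB** (bi-profile Bayes) — position-specific class-conditional
  nucleotide frequencies fitted on labeled training sequences, one profile
  from positives (p+) and one from negatives (p-); a sequence maps to its
  2L vector of (all p+ lookups, then all p- lookups).

NCP and ND are fused per base into (r, h, f, nd) quadruples; the full
local vector concatenates NCP-ND (4L), EIIP (L) and BPB (2L) blocks for a
total width of 7L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SequenceRecord

# Chemical-property truth table: base -> (ring, hydrogen-bond, functional-group).
NCP_TABLE: dict[str, tuple[int, int, int]] = {
    "A": (1, 1, 1),
    "C": (0, 0, 1),
    "G": (1, 0, 0),
    "T": (0, 1, 0),
}

# Electron-ion interaction pseudopotential energies per base.
EIIP_TABLE: dict[str, float] = {
    "T": 0.1335,
    "A": 0.1260,
    "G": 0.0806,
    "C": 0.1340,
}

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

LOCAL_PARTS = ("NCP_ND", "EIIP", "BPB")


class AlphabetError(ValueError):
    """A character outside {A, C, G, T} was encountered."""


def _check_alphabet(sequence: str) -> None:
    bad = set(sequence) - set(BASES)
    if bad:
        raise AlphabetError(f"non-ACGT characters: {sorted(bad)}")


_INDEX_LUT = np.full(256, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _INDEX_LUT[ord(_b)] = _i


def seq_indices(sequence: str) -> np.ndarray:
    """Map a validated sequence to integer base indices (A=0,C=1,G=2,T=3)."""
    if not sequence:
        raise ValueError("empty sequence")
    raw = np.frombuffer(sequence.encode("ascii", errors="strict"), dtype=np.uint8)
    idx = _INDEX_LUT[raw]
    if (idx < 0).any():
        _check_alphabet(sequence)
    return idx


def encode_ncp(nucleotide: str) -> tuple[int, int, int]:
    """Return the (r, h, f) chemical-property triple of one base."""
    try:
        return NCP_TABLE[nucleotide]
    except KeyError:
        raise AlphabetError(f"not a nucleotide: {nucleotide!r}") from None


_NCP_ROWS = np.array([NCP_TABLE[b] for b in BASES], dtype=float)
_EIIP_ROW = np.array([EIIP_TABLE[b] for b in BASES], dtype=float)


def encode_nd(sequence: str) -> np.ndarray:
    """Nucleotide-density vector: prefix frequency of each position's base."""
    idx = seq_indices(sequence)
    length = len(idx)
    onehot = np.zeros((length, 4))
    onehot[np.arange(length), idx] = 1.0
    cum = np.cumsum(onehot, axis=0)
    counts = cum[np.arange(length), idx]
    return counts / np.arange(1, length + 1)


def encode_eiip(sequence: str) -> np.ndarray:
    """Position-wise EIIP energy lookup."""
    return _EIIP_ROW[seq_indices(sequence)]


def encode_ncp_nd(sequence: str) -> np.ndarray:
    """Fused per-base (r, h, f, nd) quadruples, flattened to length 4L."""
    idx = seq_indices(sequence)
    ncp = _NCP_ROWS[idx]                      # L x 3
    nd = encode_nd(sequence)[:, None]         # L x 1
    return np.hstack([ncp, nd]).ravel()


@dataclass
class BPBModel:
    """Fitted bi-profile Bayes tables.

    ``positive_profile`` and ``negative_profile`` are L x 4 arrays of
    class-conditional nucleotide frequencies (columns ordered A, C, G, T),
    Laplace-smoothed by ``pseudocount``. ``fit_manifest`` records the
    identifiers of the training records the profiles were counted from, so
    train/test hygiene can be audited downstream.
    """

    positive_profile: np.ndarray
    negative_profile: np.ndarray
    window_length: int
    pseudocount: float
    fit_manifest: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, prof in (
            ("positive", self.positive_profile),
            ("negative", self.negative_profile),
        ):
            if prof.shape != (self.window_length, 4):
                raise ValueError(f"{name} profile shape {prof.shape} != (L, 4)")
            if not np.allclose(prof.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"{name} profile rows must sum to 1")
            if (prof < 0).any() or (prof > 1).any():
                raise ValueError(f"{name} profile outside [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "window_length": self.window_length,
            "pseudocount": self.pseudocount,
            "bases": BASES,
            "positive_profile": self.positive_profile.tolist(),
            "negative_profile": self.negative_profile.tolist(),
            "fit_manifest": list(self.fit_manifest),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "BPBModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            positive_profile=np.asarray(payload["positive_profile"], dtype=float),
            negative_profile=np.asarray(payload["negative_profile"], dtype=float),
            window_length=payload["window_length"],
            pseudocount=payload["pseudocount"],
            fit_manifest=tuple(payload.get("fit_manifest", ())),
        )


def _profile(sequences: list[str], window_length: int, pseudocount: float) -> np.ndarray:
    counts = np.full((window_length, 4), pseudocount, dtype=float)
    for seq in sequences:
        counts[np.arange(window_length), seq_indices(seq)] += 1.0
    return counts / (len(sequences) + 4.0 * pseudocount)


def fit_bpb(
    train_records: Iterable[SequenceRecord],
    window_length: int,
    pseudocount: float = 1.0,
) -> BPBModel:
    """Fit positive and negative positional profiles from training records.

    Must only ever see training-split records; the returned model carries a
    manifest of the identifiers it was fitted on for leakage audits.
    """
    records = list(train_records)
    pos = [r.sequence for r in records if r.label == 1]
    neg = [r.sequence for r in records if r.label == 0]
    if not pos or not neg:
        raise ValueError("both classes must be present in BPB training data")
    for r in records:
        if len(r.sequence) != window_length:
            raise ValueError(
                f"record {r.identifier!r} length {len(r.sequence)} != {window_length}"
            )
    return BPBModel(
        positive_profile=_profile(pos, window_length, pseudocount),
        negative_profile=_profile(neg, window_length, pseudocount),
        window_length=window_length,
        pseudocount=pseudocount,
        fit_manifest=tuple(r.identifier for r in records),
    )


def encode_bpb(sequence: str, model: BPBModel) -> np.ndarray:
    """Look up p+ then p- for each position's base: a 2L vector."""
    idx = seq_indices(sequence)
    if len(idx) != model.window_length:
        raise ValueError(f"sequence length {len(idx)} != {model.window_length}")
    pos_idx = np.arange(model.window_length)
    return np.concatenate(
        [model.positive_profile[pos_idx, idx], model.negative_profile[pos_idx, idx]]
    )


def local_feature_names(window_length: int, parts: Sequence[str]) -> list[str]:
    """Flat 0-based names per block: NCPND_k, EIIP_k, BPB_k."""
    widths = {"NCP_ND": 4 * window_length, "EIIP": window_length, "BPB": 2 * window_length}
    prefixes = {"NCP_ND": "NCPND", "EIIP": "EIIP", "BPB": "BPB"}
    names: list[str] = []
    for part in LOCAL_PARTS:
        if part in parts:
            names.extend(f"{prefixes[part]}_{k}" for k in range(widths[part]))
    return names


def encode_local(
    sequence: str,
    model: BPBModel | None = None,
    parts: Sequence[str] = LOCAL_PARTS,
) -> np.ndarray:
    """Concatenate the requested blocks in fixed order NCP_ND, EIIP, BPB."""
    if not parts:
        raise ValueError("parts must be non-empty")
    unknown = set(parts) - set(LOCAL_PARTS)
    if unknown:
        raise ValueError(f"unknown parts {sorted(unknown)}")
    blocks = []
    if "NCP_ND" in parts:
        blocks.append(encode_ncp_nd(sequence))
    if "EIIP" in parts:
        blocks.append(encode_eiip(sequence))
    if "BPB" in parts:
        if model is None:
            raise ValueError("BPB part requires a fitted BPBModel")
        blocks.append(encode_bpb(sequence, model))
    return np.concatenate(blocks)


class BPBEncoder(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer for the bi-profile Bayes encoding.

    ``fit`` expects sequences and binary labels (training split only);
    ``transform`` maps any sequence of the same window length to its 2L
    probability-lookup vector.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X: Sequence[str], y: Sequence[int], ids: Sequence[str] | None = None):
        if ids is None:
            ids = [f"train_{i}" for i in range(len(X))]
        records = [
            SequenceRecord(ident, seq, int(label))
            for ident, seq, label in zip(ids, X, y, strict=True)
        ]
        window_length = len(records[0].sequence)
        self.model_ = fit_bpb(records, window_length, self.pseudocount)
        self.window_length_ = window_length
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        return np.array([encode_bpb(seq, self.model_) for seq in X])


class LocalEncoder(BaseEstimator, TransformerMixin):
    """Full local encoding: NCP-ND + EIIP + BPB blocks, width 7L by default.

    Stateless except for the BPB profiles, which are fitted from the
    (training) sequences and labels handed to :meth:`fit`. Any subset of
    blocks may be selected via ``parts`` for ablation runs.
    """

    def __init__(self, parts: Sequence[str] = LOCAL_PARTS, pseudocount: float = 1.0):
        self.parts = tuple(parts)
        self.pseudocount = pseudocount

    def fit(self, X: Sequence[str], y: Sequence[int] | None = None,
            ids: Sequence[str] | None = None):
        if not self.parts:
            raise ValueError("parts must be non-empty")
        seqs = list(X)
        self.window_length_ = len(seqs[0])
        if "BPB" in self.parts:
            if y is None:
                raise ValueError("BPB part requires labels at fit time")
            self.bpb_ = BPBEncoder(self.pseudocount).fit(seqs, y, ids=ids)
        else:
            self.bpb_ = None
        self.feature_names_ = local_feature_names(self.window_length_, self.parts)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        model = self.bpb_.model_ if self.bpb_ is not None else None
        mat = np.array([encode_local(seq, model, self.parts) for seq in X])
        return mat

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_, dtype=object)
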