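"""File formats: FASTA sequences, signal tables, truth alignments, config.

Everything is plain text: signals are single-column floats (one sample per
line), truth alignments are 3-column TSV (read_id, kmer_index, duration),
metrics are TSV, the Gaussian emission table is 3-column delimited text
(kmer, mean, std), and the model configuration is YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .alphabet import KmerAlphabet, build_kmer_alphabet
from .models import (
    DurationModel,
    GaussianObservation,
    TransitionModel,
    build_duration_model,
    count_transitions_from_reference,
    uniform_shift_transitions,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_signal",
    "write_signal",
    "read_truth_table",
    "write_truth_table",
    "write_metrics",
    "read_gaussian_table",
    "write_gaussian_table",
    "ModelConfig",
    "load_model_config",
]


class ParseError(ValueError):
    pass


def _require(path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return path


def read_fasta(path) -> dict[str, str]:
    """Ordered mapping of record id -> sequence."""
    path = _require(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_signal(path) -> np.ndarray:
    """Single-column float text, one current sample per line."""
    path = _require(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric signal line {line!r}")
    if not values:
        raise ParseError(f"{path}: empty signal file")
    return np.array(values)


def write_signal(path, signal) -> None:
    np.savetxt(path, np.asarray(signal, dtype=float), fmt="%.12g")


def read_truth_table(path) -> pd.DataFrame:
    """TSV with columns read_id, kmer_index, duration."""
    df = pd.read_csv(_require(path), sep="\t", dtype={"read_id": str})
    missing = {"read_id", "kmer_index", "duration"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_truth_table(path, reads) -> None:
    rows = [
        (r.read_id, int(k), int(d))
        for r in reads
        for k, d in zip(r.truth_kmers, r.truth_durations)
    ]
    pd.DataFrame(rows, columns=["read_id", "kmer_index", "duration"]).to_csv(
        path, sep="\t", index=False
    )


def write_metrics(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_matrix(path, matrix, fmt: str = "%.8g") -> None:
    """Tab-delimited dump of a trellis/occupancy table (debugging aid)."""
    np.savetxt(path, np.asarray(matrix), fmt=fmt, delimiter="\t")


def read_gaussian_table(path, alphabet: KmerAlphabet) -> GaussianObservation:
    """3-column delimited text: kmer string, mean, std (any whitespace)."""
    df = pd.read_csv(_require(path), sep=r"\s+", names=["kmer", "mean", "std"],
                     comment="#", header=None)
    mu = np.zeros(alphabet.size)
    sigma = np.zeros(alphabet.size)
    seen = np.zeros(alphabet.size, dtype=bool)
    for row in df.itertuples(index=False):
        idx = alphabet.encode(str(row.kmer))
        mu[idx], sigma[idx], seen[idx] = float(row.mean), float(row.std), True
    if not seen.all():
        raise ParseError(f"{path}: table covers {seen.sum()} of {alphabet.size} k-mers")
    return GaussianObservation(mu=mu, sigma=sigma)


def write_gaussian_table(path, obs: GaussianObservation, alphabet: KmerAlphabet) -> None:
    with open(path, "w") as fh:
        for i in range(alphabet.size):
            fh.write(f"{alphabet.decode(i)}\t{obs.mu[i]:.8g}\t{obs.sigma[i]:.8g}\n")


# ---------------------------------------------------------------------------
# model configuration


class ModelConfig:
    """Bundle of alphabet, transition, duration and observation models."""

    def __init__(
        self,
        alphabet: KmerAlphabet,
        transitions: TransitionModel,
        durations: DurationModel,
        observation: GaussianObservation | None,
    ):
        self.alphabet = alphabet
        self.transitions = transitions
        self.durations = durations
        self.observation = observation


def load_model_config(path) -> ModelConfig:
    """Read a YAML model configuration.

    Keys: ``k`` (int), ``bases`` (list, default ACGT), ``transitions``
    (``mode: uniform_shift | reference_counts`` with optional
    ``reference_fasta`` and ``pseudocount``), ``dwell`` (``a``, ``b``,
    ``dbar``, ``gamma`` — number or "mean-matched"), ``gaussian_table``
    (path to the 3-column emission table, optional).  Relative paths are
    resolved against the config file's directory.
    """
    path = _require(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    alphabet = build_kmer_alphabet(
        int(raw.get("k", 5)), tuple(raw.get("bases", ("A", "C", "G", "T")))
    )
    tcfg = raw.get("transitions", {"mode": "uniform_shift"})
    mode = tcfg.get("mode", "uniform_shift")
    if mode == "uniform_shift":
        transitions = uniform_shift_transitions(
            alphabet, self_loops=bool(tcfg.get("self_loops", True))
        )
    elif mode == "reference_counts":
        ref_path = Path(tcfg["reference_fasta"])
        if not ref_path.is_absolute():
            ref_path = path.parent / ref_path
        ref = "".join(read_fasta(ref_path).values())
        transitions = count_transitions_from_reference(
            ref, alphabet, pseudocount=float(tcfg.get("pseudocount", 1.0))
        )
    else:
        raise ParseError(f"{path}: unknown transition mode {mode!r}")
    dcfg = raw.get("dwell", {})
    durations = build_duration_model(
        a=float(dcfg.get("a", 8.0)),
        b=float(dcfg.get("b", 4.0)),
        dbar=int(dcfg.get("dbar", 12)),
        gamma=dcfg.get("gamma", "mean-matched"),
    )
    observation = None
    if raw.get("gaussian_table"):
        gpath = Path(raw["gaussian_table"])
        if not gpath.is_absolute():
            gpath = path.parent / gpath
        observation = read_gaussian_table(gpath, alphabet)
    return ModelConfig(alphabet, transitions, durations, observation)
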