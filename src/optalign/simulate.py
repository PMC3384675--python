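"""Synthetic benchmark generation.

Builds the inputs of the mutation benchmark: a uniform-random database
(standing in for a 1 Mbp bacterial-genome extract), a set of queries
extracted at random positions with random lengths, and mutated copies of
each query at a range of substitution rates.  Defaults reproduce the study
conditions: a 1,000,000 bp database, 303 queries of 50-4,500 bp, and seven
noise levels 0-60% in steps of 10 (303 x 7 = 2,121 query records).

The substitution model changes exactly ``round(rate * length)`` distinct
positions, each replaced by a base drawn uniformly from the *other* three
bases, so the realized mismatch fraction equals the nominal rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import codec

__all__ = [
    "QueryRecord",
    "Benchmark",
    "random_database",
    "extract_queries",
    "mutate",
    "build_benchmark",
    "DEFAULT_NOISE_LEVELS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_NOISE_LEVELS: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class QueryRecord:
    """One query with its ground truth.

    ``true_start`` is the 0-based database coordinate the (unmutated parent
    of the) query was extracted from; at ``noise_level`` 0 the sequence is
    an exact substring of the database at that coordinate.
    """

    id: str
    sequence: str
    true_start: int
    length: int
    noise_level: float = 0.0


def random_database(n_bases: int, seed: int | np.random.Generator | None = None) -> str:
    """I.i.d. uniform DNA string of ``n_bases`` over {A, C, G, T}."""
    if n_bases <= 0:
        raise ValueError("n_bases must be >= 1")
    rng = _rng(seed)
    return _BASES[rng.integers(0, 4, n_bases)].tobytes().decode("ascii")


def extract_queries(
    db: str,
    n_queries: int = 303,
    min_len: int = 50,
    max_len: int = 4500,
    seed: int | np.random.Generator | None = None,
) -> list[QueryRecord]:
    """Extract queries of uniform-random length at uniform-random positions."""
    if min_len < 1 or min_len > max_len:
        raise ValueError(f"need 1 <= min_len <= max_len, got [{min_len}, {max_len}]")
    if max_len > len(db):
        raise ValueError(f"max_len ({max_len}) exceeds the database length ({len(db)})")
    rng = _rng(seed)
    width = len(str(max(n_queries - 1, 0)))
    records = []
    for i in range(n_queries):
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, len(db) - length + 1))
        records.append(
            QueryRecord(
                id=f"q{i:0{max(width, 3)}d}",
                sequence=db[start : start + length],
                true_start=start,
                length=length,
                noise_level=0.0,
            )
        )
    return records


def mutate(
    sequence: str,
    rate: float,
    seed: int | np.random.Generator | None = None,
    lenient: bool = False,
) -> str:
    """Substitute ``round(rate * length)`` distinct positions of a sequence.

    Positions are chosen uniformly without replacement; each chosen base is
    replaced by one of the other three bases (guaranteed change), or by any
    of the four when ``lenient=True``.  Length is preserved.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must be in [0, 1], got {rate}")
    k = round(rate * len(sequence))
    if k == 0:
        return sequence
    rng = _rng(seed)
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    idx = np.searchsorted(_BASES, raw)  # A,C,G,T are sorted ASCII codes
    positions = rng.choice(len(sequence), size=k, replace=False)
    if lenient:
        idx[positions] = rng.integers(0, 4, size=k)
    else:
        idx[positions] = (idx[positions] + rng.integers(1, 4, size=k)) % 4
    raw = _BASES[idx]
    return raw.tobytes().decode("ascii")


@dataclass
class Benchmark:
    """A generated benchmark instance: database plus all query sets."""

    db: str
    queries: list[QueryRecord]
    noise_levels: tuple[float, ...]
    scene_width: int = 100
    scene_height: int = 100
    seed: int | None = None

    def queries_at(self, level: float) -> list[QueryRecord]:
        return [q for q in self.queries if q.noise_level == level]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [q.id for q in self.queries],
                "true_start": [q.true_start for q in self.queries],
                "length": [q.length for q in self.queries],
                "noise_level": [q.noise_level for q in self.queries],
            }
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Serialize to ``db.fasta``, ``queries.fasta`` and ``truth.tsv``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "db": out / "db.fasta",
            "queries": out / "queries.fasta",
            "truth": out / "truth.tsv",
        }
        codec.write_fasta([("db", self.db)], paths["db"])
        codec.write_fasta([(q.id, q.sequence) for q in self.queries], paths["queries"])
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def build_benchmark(
    db_size: int = 1_000_000,
    n_queries: int = 303,
    noise_levels: Sequence[float] = DEFAULT_NOISE_LEVELS,
    scene_width: int = 100,
    scene_height: int = 100,
    min_len: int = 50,
    max_len: int = 4500,
    seed: int | None = None,
) -> Benchmark:
    """Generate database, base queries and mutated sets for every noise level.

    With the defaults this yields ``303 x 7 = 2,121`` query records.  Child
    random streams for the database, the extraction and each mutation level
    are spawned from ``seed``, so the whole bundle is reproducible.
    """
    levels = tuple(sorted(float(l) for l in noise_levels))
    streams = np.random.SeedSequence(seed).spawn(2 + len(levels))
    db = random_database(db_size, np.random.default_rng(streams[0]))
    base = extract_queries(
        db, n_queries, min_len=min_len, max_len=max_len, seed=np.random.default_rng(streams[1])
    )
    queries: list[QueryRecord] = []
    for level, stream in zip(levels, streams[2:]):
        rng = np.random.default_rng(stream)
        if level == 0.0:
            queries.extend(base)
            continue
        for q in base:
            queries.append(
                QueryRecord(
                    id=f"{q.id}_m{int(round(level * 100)):02d}",
                    sequence=mutate(q.sequence, level, rng),
                    true_start=q.true_start,
                    length=q.length,
                    noise_level=level,
                )
            )
    return Benchmark(
        db=db,
        queries=queries,
        noise_levels=levels,
        scene_width=scene_width,
        scene_height=scene_height,
        seed=seed,
    )
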