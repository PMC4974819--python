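"""FASTA input, dot-bracket output, and scoring-scheme config files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Tuple, Union

from Bio import SeqIO

from .core import Folding, RnaSequence, ScoringScheme, normalize_sequence

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> List[Tuple[str, RnaSequence]]:
    """Read a (multi-record) FASTA file into normalized RNA sequences.

    DNA-style T residues are mapped to U; any other non-ACGU symbol is an
    error naming the record it occurred in.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found (empty or malformed file)")
    out: List[Tuple[str, RnaSequence]] = []
    for idx, rec in enumerate(records, start=1):
        raw = str(rec.seq)
        if not raw.strip():
            raise ValueError(f"{path}: record {idx} ({rec.id!r}) has an empty sequence")
        try:
            out.append((rec.id, normalize_sequence(raw)))
        except ValueError as exc:
            raise ValueError(f"{path}: record {idx} ({rec.id!r}): {exc}") from exc
    return out


def dotbracket(seq: RnaSequence, folding: Folding) -> str:
    """Dot-bracket string: '(' at k and ')' at l for each pair, '.' elsewhere."""
    folding.validate(seq.n)
    chars = ["."] * seq.n
    for k, l in folding.pairs:
        chars[k] = "("
        chars[l] = ")"
    return "".join(chars)


def write_dotbracket(seq: RnaSequence, folding: Folding, path: PathLike) -> None:
    """Write two lines -- the sequence, then its dot-bracket structure."""
    text = f"{seq.residues}\n{dotbracket(seq, folding)}\n"
    Path(path).write_text(text)


def load_scoring_scheme(path: PathLike) -> ScoringScheme:
    """Load a JSON map of two-letter pair strings to non-negative integer
    scores, e.g. ``{"GC": 1, "AU": 1}``; both orientations are implied."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: scoring scheme must be a JSON object")
    return ScoringScheme.from_pairs(data)
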