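"""Plain-text genome format.

One record per genome: an optional ``>name`` header line followed by one
line of whitespace- or comma-separated integers.  A leading ``-`` marks a
reverse-oriented gene; records containing any explicit sign are read as
signed.  Records are implicitly circular.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

from .genomes import Genome, SignedGenome, UnsignedGenome

__all__ = ["read_genomes", "write_genomes", "parse_genome_line", "format_genome"]

_SPLIT = re.compile(r"[,\s]+")


def parse_genome_line(line: str, signed: Optional[bool] = None) -> Genome:
    """Parse one record line; ``signed=None`` auto-detects from +/- prefixes."""
    tokens = [t for t in _SPLIT.split(line.strip()) if t]
    if not tokens:
        raise ValueError("empty genome record")
    values = [int(t) for t in tokens]
    if signed is None:
        signed = any(t.startswith(("+", "-")) for t in tokens)
    if signed:
        return SignedGenome(values)
    return UnsignedGenome(values)


def format_genome(genome: Genome) -> str:
    if isinstance(genome, SignedGenome):
        return " ".join(f"{g:+d}" for g in genome.order)
    return " ".join(str(g) for g in genome.order)


def read_genomes(
    path: Union[str, Path, TextIO], signed: Optional[bool] = None
) -> list[Genome]:
    """Read all genome records from a file (or open text handle)."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    genomes = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith((">", "#")):
            continue
        genomes.append(parse_genome_line(line, signed=signed))
    if not genomes:
        raise ValueError("no genome records found")
    return genomes


def write_genomes(
    path: Union[str, Path],
    genomes: Sequence[Genome],
    names: Optional[Sequence[str]] = None,
) -> None:
    """Write genomes in the text format, one ``>name`` + record pair each."""
    if names is not None and len(names) != len(genomes):
        raise ValueError("names and genomes must have equal length")
    with open(path, "w") as fh:
        for i, g in enumerate(genomes):
            name = names[i] if names is not None else f"genome_{i + 1}"
            fh.write(f">{name}\n{format_genome(g)}\n")
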