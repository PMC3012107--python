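"""Reading and writing p-value files in the SGoF program format.

The format is a plain-text file whose first non-blank line is an integer S
(the total number of tests), followed by S lines of whitespace-separated
``identifier p-value`` pairs.  Identifiers may be numbers or strings and the
list need not be sorted.  Blank lines and lines starting with ``#`` are
skipped and not counted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .core import PValueSet
from .simulation import generate_pvalues

__all__ = ["FormatError", "read_pvalue_file", "write_pvalue_file", "write_fixture"]


class FormatError(ValueError):
    """Raised when an input file violates the SGoF p-value format."""


def read_pvalue_file(path, lenient: bool = False) -> PValueSet:
    """Parse an SGoF-format p-value file into a :class:`PValueSet`.

    Input order is preserved.  Rows with more than two fields are rejected
    unless ``lenient`` is True, in which case fields beyond the second are
    ignored.  Errors carry 1-based line numbers.
    """
    path = Path(path)
    declared_count: Optional[int] = None
    ids: list[str] = []
    pvals: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if declared_count is None:
                try:
                    declared_count = int(line)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: expected an integer test count, got {line!r}"
                    ) from None
                if declared_count < 0:
                    raise FormatError(
                        f"{path}:{lineno}: test count must be non-negative, got {declared_count}"
                    )
                continue
            fields = line.split()
            if len(fields) != 2 and not (lenient and len(fields) > 2):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 whitespace-separated fields "
                    f"(identifier, p-value), got {len(fields)}"
                )
            ident, pstr = fields[0], fields[1]
            try:
                p = float(pstr)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unparseable p-value {pstr!r}"
                ) from None
            if not 0.0 <= p <= 1.0:
                raise FormatError(
                    f"{path}:{lineno}: p-value {p} outside the interval [0, 1]"
                )
            ids.append(ident)
            pvals.append(p)
    if declared_count is None:
        raise FormatError(f"{path}: empty file; expected a test count header")
    if declared_count != len(ids):
        raise FormatError(
            f"{path}: header declares {declared_count} tests but {len(ids)} "
            f"data rows were found"
        )
    return PValueSet(ids=ids, pvalues=pvals)


def write_pvalue_file(pset: PValueSet, path) -> None:
    """Write a :class:`PValueSet` in the SGoF input format.

    p-values are serialised with 15 significant digits so a read/write
    round-trip is lossless at double precision.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(pset)}\n")
        for ident, p in zip(pset.ids, pset.pvalues):
            fh.write(f"{ident} {p:.15g}\n")


def write_fixture(
    path, S: int, effect_proportion: float, w: float, seed: int
) -> PValueSet:
    """Generate a synthetic mixture p-value file plus a truth sidecar.

    The main file is SGoF-format input; ``<path>.truth`` lists
    ``identifier 0|1`` (1 = genuine effect) for use in power evaluations.
    Returns the generated set.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    pset = generate_pvalues(S, effect_proportion, w, rng)
    write_pvalue_file(pset, path)
    truth_path = Path(str(path) + ".truth")
    with truth_path.open("w", encoding="utf-8") as fh:
        for ident, t in zip(pset.ids, pset.truth):
            fh.write(f"{ident} {int(t)}\n")
    return pset
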