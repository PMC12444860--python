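"""Small shared helpers: atomic file writes and seeded RNG streams."""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np


@contextmanager
def atomic_write(path: str | os.PathLike, mode: str = "w"):
    """Write to a temporary file in the target directory, then rename.

    The rename is atomic on POSIX, so readers never observe a half-written
    file; on failure the temporary file is removed and the target untouched.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def atomic_replace(path: str | os.PathLike):
    """Return a temp path next to `path`; caller writes it then calls os.replace."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    return tmp


def rng_stream(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic, independent RNG stream keyed by (seed, *stream)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))
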