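"""Shared helpers: seeding, survival-outcome coercion, standardization."""

from __future__ import annotations

import numpy as np


def rng_from(seed) -> np.random.Generator:
    """Return a numpy Generator from a seed, Generator or SeedSequence."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed.

    Children are produced with :class:`numpy.random.SeedSequence` so that
    replicate-level streams are statistically independent and reproducible.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def check_survival_y(y, n: int | None = None):
    """Coerce a survival outcome into ``(time, status)`` float/int arrays.

    Accepts a scikit-survival structured array (one boolean event field and
    one numeric time field, in either order), a ``(time, status)`` tuple of
    arrays, or an ``(n, 2)`` array with columns time, status.
    """
    if hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = y.dtype.names
        if len(names) != 2:
            raise ValueError("structured survival outcome must have exactly two fields")
        a, b = (np.asarray(y[name]) for name in names)
        if a.dtype == bool or names[0].lower() in ("event", "status", "delta"):
            status, time = a, b
        else:
            time, status = a, b
    elif isinstance(y, (tuple, list)) and len(y) == 2:
        time, status = y
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("survival outcome must be structured, a (time, status) pair, or n x 2")
        time, status = arr[:, 0], arr[:, 1]
    time = np.asarray(time, dtype=float).ravel()
    status = np.asarray(status).astype(int).ravel()
    if time.shape != status.shape:
        raise ValueError("time and status lengths differ")
    if n is not None and time.size != n:
        raise ValueError(f"survival outcome has {time.size} subjects, expected {n}")
    if np.any(time <= 0):
        raise ValueError("observed times must be positive")
    if not np.isin(status, (0, 1)).all():
        raise ValueError("status must be 0 (censored) or 1 (event)")
    return time, status


def as_structured_y(time, status):
    """Pack ``(time, status)`` into a scikit-survival style structured array."""
    y = np.empty(len(time), dtype=[("event", bool), ("time", float)])
    y["event"] = np.asarray(status).astype(bool)
    y["time"] = np.asarray(time, dtype=float)
    return y
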