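"""The "true patchiness" statistic K for along-transect presence sequences.

*Sabellaria spinulosa* reef tends to grow in consolidated clumps rather than
uniformly at random over the seabed. To quantify that tendency along a video
tow, each 5-s segment is reduced to a presence value (1 if any reef cover
was observed, 0 if none; missing where the seabed was obscured). A *patch*
is a maximal run of consecutive 1s. The statistic

    K = p_o / p_r

compares the mean observed patch size ``p_o`` with the mean patch size
``p_r`` expected if the same number of presence observations were arranged
at random along the tow. ``p_r`` is estimated by randomizing the sequence
1,000 times (uniform permutations, preserving the counts of 1s and 0s),
taking the mean patch size of each randomization, and averaging. K > 1
indicates patchiness: observed patches are larger than chance arrangement
would produce. The permutation p-value is the proportion of randomized mean
patch sizes strictly greater than the observed one.

Missing values are deleted before patch extraction *and* before
randomization, so a missing observation between two presence runs bridges
them into a single patch and the null operates on the same cleaned string.

For short sequences :func:`exact_null` enumerates every distinct arrangement
of the multiset, providing an exact reference against which the randomized
estimates are validated.
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np

from .status import StatusClass

if TYPE_CHECKING:  # pragma: no cover
    from .transect import TransectSeries

__all__ = [
    "PresenceSequence",
    "PatchSet",
    "PatchinessResult",
    "TowSummary",
    "parse_sequence",
    "clean_sequence",
    "extract_patches",
    "mean_patch_size",
    "randomized_null",
    "exact_null",
    "k_statistic",
    "summarize_tow",
    "tow_seed",
]

logger = logging.getLogger(__name__)

#: Default number of randomizations used to estimate the null mean patch size.
DEFAULT_N_RANDOMIZATIONS = 1000

#: Default cap on the number of distinct arrangements exact_null will enumerate.
EXACT_ENUMERATION_CAP = 10**6


@dataclass(frozen=True)
class PresenceSequence:
    """Ordered presence values for one tow: 0, 1, or ``None`` (missing)."""

    values: tuple[int | None, ...]
    tow_id: str = ""

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("presence sequence must be non-empty")
        for v in self.values:
            if v not in (0, 1, None):
                raise ValueError(f"presence values must be 0, 1 or missing; got {v!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PatchSet:
    """Patch sizes extracted from a binary presence sequence, in tow order."""

    sizes: tuple[int, ...]
    n_ones: int
    n_zeros: int

    def __post_init__(self) -> None:
        if sum(self.sizes) != self.n_ones:
            raise ValueError("patch sizes must sum to the number of 1s")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("patch sizes must be positive")

    def __len__(self) -> int:
        return len(self.sizes)


@dataclass(frozen=True)
class PatchinessResult:
    """K statistic with its randomization diagnostics for one tow."""

    tow_id: str
    p_o: float
    p_r: float
    k: float
    p_value: float
    n_randomizations: int
    seed: int
    n_ties: int
    n_ones: int
    n_zeros: int
    tie_corrected: bool = False
    null_means: tuple[float, ...] | None = None


@dataclass(frozen=True)
class TowSummary:
    """One summary-table row per tow: status breakdown and patch statistics.

    Percentages are of valid (non-missing) segments and sum to 100. The
    patchiness fields are ``None`` when the statistic is undefined for the
    tow (no patches, or a degenerate all-presence/all-absence sequence).
    """

    tow_id: str
    n_segments: int
    n_valid: int
    pct_no_reef: float
    pct_not_reef: float
    pct_low: float
    pct_medium: float
    pct_high: float
    n_patches: int
    mean_patch_len: float | None
    median_patch_len: float | None
    patch_size_min: int | None
    patch_size_max: int | None
    k: float | None
    p_value: float | None


# ---------------------------------------------------------------------------
# Sequence plumbing


def parse_sequence(text: str, tow_id: str = "") -> PresenceSequence:
    """Parse a presence-sequence literal such as ``"10.110"``.

    ``1`` and ``0`` are presence/absence; ``.`` or ``*`` mark a missing
    observation. Whitespace and commas are ignored, so the spaced form
    ``"1 0 0 1 1 1 0 0 1 1 0"`` parses equally.
    """
    values: list[int | None] = []
    for ch in text:
        if ch in "1":
            values.append(1)
        elif ch == "0":
            values.append(0)
        elif ch in ".*":
            values.append(None)
        elif ch in " ,\t\n":
            continue
        else:
            raise ValueError(f"invalid character in sequence literal: {ch!r}")
    return PresenceSequence(tuple(values), tow_id=tow_id)


def _as_values(seq: "PresenceSequence | Sequence[int | None]") -> tuple[int | None, ...]:
    if isinstance(seq, PresenceSequence):
        return seq.values
    return tuple(seq)


def clean_sequence(seq: "PresenceSequence | Sequence[int | None]") -> np.ndarray:
    """Delete missing values and concatenate the remainder, in order.

    A missing value between two presence runs therefore bridges them: the
    cleaned form of ``0 1 * 1 1 0`` is ``0 1 1 1 0``, a single patch of 3.
    """
    values = _as_values(seq)
    if not values:
        raise ValueError("presence sequence must be non-empty")
    cleaned = [v for v in values if v is not None]
    if not cleaned:
        raise ValueError("no usable segments: all observations are missing")
    arr = np.asarray(cleaned, dtype=np.int8)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("presence values must be 0 or 1")
    return arr


def extract_patches(binary: Sequence[int] | np.ndarray) -> PatchSet:
    """Maximal runs of 1s in a gap-free binary sequence, in tow order.

    A run terminated by the end of the sequence counts as a patch (this
    keeps the sizes summing to the number of 1s). All-absence input yields
    an empty :class:`PatchSet`.
    """
    arr = np.asarray(binary, dtype=np.int8)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("binary sequence must be non-empty and 1-D")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("sequence contains non-binary values; clean it first")
    padded = np.concatenate(([0], arr, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    sizes = tuple(int(s) for s in (ends - starts))
    n_ones = int(arr.sum())
    return PatchSet(sizes=sizes, n_ones=n_ones, n_zeros=int(arr.size - n_ones))


def mean_patch_size(patches: PatchSet) -> float:
    """Arithmetic mean patch size, ``p_o`` for the observed sequence."""
    if not patches.sizes:
        raise ValueError("undefined: no presence observed (no patches)")
    return patches.n_ones / len(patches.sizes)


# ---------------------------------------------------------------------------
# Randomization null


def _check_non_degenerate(arr: np.ndarray) -> tuple[int, int]:
    n_ones = int(arr.sum())
    n_zeros = int(arr.size - n_ones)
    if n_ones == 0 or n_zeros == 0:
        raise ValueError(
            "null degenerate: the sequence is constant "
            f"({n_ones} ones, {n_zeros} zeros), so every permutation is "
            "identical and K is uninformative"
        )
    return n_ones, n_zeros


def _null_mean_patch_sizes(
    arr: np.ndarray, n_randomizations: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean patch size of each of ``n_randomizations`` uniform permutations.

    The number of patches in a binary string equals the number of 1s minus
    the number of adjacent (1, 1) pairs, so the per-permutation mean is
    computed without explicit run-length decoding. Permutations are drawn in
    blocks to bound memory on long sequences. They are applied to the
    canonical (sorted) arrangement of the multiset, so any two observed
    sequences with the same 0/1 counts share the identical null sample for
    a given seed — the null depends on the multiset only.
    """
    n_ones = int(arr.sum())
    canonical = np.zeros(arr.size, dtype=np.int8)
    canonical[:n_ones] = 1
    out = np.empty(n_randomizations, dtype=np.float64)
    block = max(1, min(n_randomizations, 4_000_000 // max(1, arr.size)))
    done = 0
    while done < n_randomizations:
        m = min(block, n_randomizations - done)
        perms = np.tile(canonical, (m, 1))
        rng.permuted(perms, axis=1, out=perms)
        adjacent = np.count_nonzero(perms[:, 1:] & perms[:, :-1], axis=1)
        out[done : done + m] = n_ones / (n_ones - adjacent)
        done += m
    return out


def randomized_null(
    binary: Sequence[int] | np.ndarray,
    n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Estimate the null mean patch size ``p_r`` by permutation.

    Each randomization is a uniform permutation of the cleaned binary
    values, preserving the counts of 1s and 0s: conditioning on prevalence
    isolates the *arrangement* of presence from its abundance. Returns
    ``(p_r, null_means)`` where ``null_means`` holds the mean patch size of
    every randomization and ``p_r`` is their average. Reproducible for a
    fixed integer seed.
    """
    arr = np.asarray(binary, dtype=np.int8)
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    _check_non_degenerate(arr)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    null_means = _null_mean_patch_sizes(arr, n_randomizations, rng)
    return float(null_means.mean()), null_means


def exact_null(
    binary: Sequence[int] | np.ndarray,
    cap: int = EXACT_ENUMERATION_CAP,
    p_o: float | None = None,
) -> tuple[float, float]:
    """Exact ``p_r`` and strictly-greater p-value by full enumeration.

    Enumerates all ``C(n, k)`` distinct arrangements of the multiset of k
    1s and n-k 0s, each equally weighted (as under uniform permutation),
    and averages their mean patch sizes. Serves as the brute-force oracle
    for :func:`randomized_null` and :func:`k_statistic` on short sequences.

    Parameters
    ----------
    binary
        The observed gap-free sequence; its own mean patch size is the
        reference for the p-value unless ``p_o`` overrides it.
    cap
        Maximum number of arrangements to enumerate (error above it).
    """
    arr = np.asarray(binary, dtype=np.int8)
    n_ones, n_zeros = _check_non_degenerate(arr)
    n = arr.size
    n_arrangements = math.comb(n, n_ones)
    if n_arrangements > cap:
        raise ValueError(
            f"{n_arrangements} distinct arrangements exceed the enumeration "
            f"cap ({cap}); use randomized_null instead"
        )
    if p_o is None:
        p_o = mean_patch_size(extract_patches(arr))
    total = 0.0
    n_greater = 0
    # A k-subset of positions determines the arrangement; its number of
    # patches is 1 + (# of non-adjacent consecutive chosen positions).
    for ones_pos in itertools.combinations(range(n), n_ones):
        n_patches = 1 + sum(
            1 for a, b in zip(ones_pos, ones_pos[1:]) if b - a > 1
        )
        mean = n_ones / n_patches
        total += mean
        if mean > p_o:
            n_greater += 1
    p_r_exact = total / n_arrangements
    p_value_exact = n_greater / n_arrangements
    return p_r_exact, p_value_exact


def k_statistic(
    seq: "PresenceSequence | Sequence[int | None]",
    n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
    seed: int | np.random.Generator = 0,
    tie_corrected: bool = False,
    keep_null: bool = False,
) -> PatchinessResult:
    """The true-patchiness statistic K = p_o / p_r with permutation p-value.

    Missing values are removed first; the same cleaned string feeds both
    the observed mean patch size and the randomization null. The p-value is
    the proportion of randomized mean patch sizes *strictly greater* than
    the observed one, as in the original formulation; ``n_ties`` reports how
    many randomized means equalled ``p_o`` exactly. With
    ``tie_corrected=True`` the Manly-style estimate
    ``(greater + ties + 1) / (n + 1)`` is reported instead.

    Raises
    ------
    ValueError
        If the cleaned sequence is all-presence or all-absence: K is
        undefined there (every permutation is identical), and silently
        reporting a default would corrupt monitoring time series.
    """
    tow_id = seq.tow_id if isinstance(seq, PresenceSequence) else ""
    arr = clean_sequence(seq)
    n_ones, n_zeros = _check_non_degenerate(arr)
    p_o = mean_patch_size(extract_patches(arr))
    seed_out = seed if isinstance(seed, int) else -1
    p_r, null_means = randomized_null(arr, n_randomizations, seed)
    n_greater = int(np.count_nonzero(null_means > p_o))
    n_ties = int(np.count_nonzero(null_means == p_o))
    if tie_corrected:
        p_value = (n_greater + n_ties + 1) / (n_randomizations + 1)
    else:
        p_value = n_greater / n_randomizations
    return PatchinessResult(
        tow_id=tow_id,
        p_o=p_o,
        p_r=p_r,
        k=p_o / p_r,
        p_value=p_value,
        n_randomizations=n_randomizations,
        seed=seed_out,
        n_ties=n_ties,
        n_ones=n_ones,
        n_zeros=n_zeros,
        tie_corrected=tie_corrected,
        null_means=tuple(float(x) for x in null_means) if keep_null else None,
    )


# ---------------------------------------------------------------------------
# Tow summaries


def tow_seed(seed: int, tow_id: str) -> int:
    """Deterministic per-tow sub-seed derived from (run seed, tow id)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(tow_id.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


_PCT_FIELDS = {
    StatusClass.NO_REEF: "pct_no_reef",
    StatusClass.NOT_A_REEF: "pct_not_reef",
    StatusClass.LOW: "pct_low",
    StatusClass.MEDIUM: "pct_medium",
    StatusClass.HIGH: "pct_high",
}


def summarize_tow(
    series: "TransectSeries",
    n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
    seed: int = 0,
    tie_corrected: bool = False,
) -> TowSummary:
    """Summary-table row for one tow: status percentages plus patchiness.

    Percentages are computed over valid (non-missing) segments. Patch
    statistics come from the cleaned presence sequence; K and the p-value
    come from :func:`k_statistic` with a per-tow sub-seed derived from
    ``seed`` and the tow id. Where K is undefined (degenerate sequence) the
    summary is still returned with the patchiness fields ``None`` and a
    warning is logged.
    """
    statuses = [seg.status for seg in series.segments]
    valid = [s for s in statuses if s is not StatusClass.MISSING]
    if not valid:
        raise ValueError(f"tow {series.tow_id!r} has no valid segments")
    n_valid = len(valid)
    pct = {
        name: 100.0 * sum(s is cls for s in valid) / n_valid
        for cls, name in _PCT_FIELDS.items()
    }

    presence = PresenceSequence(tuple(series.presence_values()), tow_id=series.tow_id)
    cleaned = clean_sequence(presence)
    patches = extract_patches(cleaned)
    sizes = np.asarray(patches.sizes, dtype=float)

    k = p_value = None
    if patches.sizes and patches.n_zeros > 0:
        result = k_statistic(
            presence,
            n_randomizations=n_randomizations,
            seed=tow_seed(seed, series.tow_id),
            tie_corrected=tie_corrected,
        )
        k, p_value = result.k, result.p_value
    else:
        logger.warning(
            "tow %s: degenerate presence sequence (%d ones, %d zeros); "
            "K not computed",
            series.tow_id, patches.n_ones, patches.n_zeros,
        )

    return TowSummary(
        tow_id=series.tow_id,
        n_segments=len(series),
        n_valid=n_valid,
        **pct,
        n_patches=len(patches),
        mean_patch_len=float(sizes.mean()) if sizes.size else None,
        median_patch_len=float(np.median(sizes)) if sizes.size else None,
        patch_size_min=int(sizes.min()) if sizes.size else None,
        patch_size_max=int(sizes.max()) if sizes.size else None,
        k=k,
        p_value=p_value,
    )
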