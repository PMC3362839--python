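"""Core data containers: peak-height tables and binary character matrices.

Orientation is samples-as-rows, loci-as-columns everywhere. Bin labels are
fragment sizes in base pairs within [50, 500].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AflPhyloError

__all__ = ["PeakHeightTable", "BinaryCharacterMatrix"]


@dataclass
class PeakHeightTable:
    """Fluorescence intensities per sample and size bin, plus replicate pairing.

    Parameters
    ----------
    heights
        Array of shape (n_rows, n_bins) with non-negative intensities. Rows
        include replicate profiles.
    sample_ids
        Row labels, unique, replicates included.
    bin_sizes
        Strictly increasing fragment sizes (bp) in [50, 500].
    replicate_pairs
        ``(sample_id, replicate_id)`` tuples; both members must be rows.
    species_map
        Optional sample -> species labels for the non-replicate rows.
    """

    heights: np.ndarray
    sample_ids: list[str]
    bin_sizes: np.ndarray
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    species_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.bin_sizes = np.asarray(self.bin_sizes, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.replicate_pairs = [(str(a), str(b)) for a, b in self.replicate_pairs]
        if self.heights.ndim != 2:
            raise AflPhyloError("heights must be a 2-D array (samples x bins)")
        n, m = self.heights.shape
        if len(self.sample_ids) != n:
            raise AflPhyloError("sample_ids length does not match heights rows")
        if len(set(self.sample_ids)) != n:
            raise AflPhyloError("duplicate sample ids")
        if len(self.bin_sizes) != m:
            raise AflPhyloError("bin_sizes length does not match heights columns")
        if np.any(self.heights < 0):
            raise AflPhyloError("peak heights must be >= 0")
        if m and (self.bin_sizes.min() < 50 or self.bin_sizes.max() > 500):
            raise AflPhyloError("bin sizes must lie within [50, 500] bp")
        if m > 1 and np.any(np.diff(self.bin_sizes) <= 0):
            raise AflPhyloError("bin sizes must be strictly increasing")
        known = set(self.sample_ids)
        for a, b in self.replicate_pairs:
            if a not in known or b not in known:
                raise AflPhyloError(f"replicate pair ({a}, {b}) references unknown row")

    @property
    def n_rows(self) -> int:
        return self.heights.shape[0]

    @property
    def n_bins(self) -> int:
        return self.heights.shape[1]

    @property
    def replicate_row_ids(self) -> set[str]:
        """Ids of the duplicate rows (second member of each pair)."""
        return {b for _, b in self.replicate_pairs}

    def row(self, sample_id: str) -> np.ndarray:
        return self.heights[self.sample_ids.index(sample_id)]

    def primary_rows(self) -> np.ndarray:
        """Boolean mask of non-replicate rows."""
        reps = self.replicate_row_ids
        return np.array([s not in reps for s in self.sample_ids], dtype=bool)


@dataclass
class BinaryCharacterMatrix:
    """Presence/absence calls (0/1) for samples x loci with a species map."""

    calls: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    species_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise AflPhyloError("calls must be a 2-D array (samples x loci)")
        if not np.isin(self.calls, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.calls, (0, 1)))[0]
            raise AflPhyloError(
                f"non-binary call at row {bad[0]}, column {bad[1]}: "
                f"{self.calls[bad[0], bad[1]]!r}"
            )
        self.calls = self.calls.astype(np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(s) for s in self.locus_ids]
        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise AflPhyloError("sample_ids length does not match calls rows")
        if len(set(self.sample_ids)) != n:
            raise AflPhyloError("duplicate sample ids")
        if len(self.locus_ids) != m:
            raise AflPhyloError("locus_ids length does not match calls columns")
        if len(set(self.locus_ids)) != m:
            raise AflPhyloError("duplicate locus ids")
        unknown = set(self.species_map) - set(self.sample_ids)
        if unknown:
            raise AflPhyloError(f"species_map references unknown samples: {sorted(unknown)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def species(self) -> list[str]:
        """Distinct species labels, in first-appearance order over samples."""
        seen: list[str] = []
        for s in self.sample_ids:
            sp = self.species_map.get(s)
            if sp is not None and sp not in seen:
                seen.append(sp)
        return seen

    def rows_for_species(self, species: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.species_map.get(s) == species]
        if not idx:
            raise AflPhyloError(f"no samples for species {species!r}")
        return np.asarray(idx, dtype=int)

    def species_consensus(self, species: str) -> np.ndarray:
        """Per-locus majority state across a species' individuals (ties -> 1)."""
        rows = self.calls[self.rows_for_species(species)]
        return (rows.mean(axis=0) >= 0.5).astype(np.int8)

    # -- subsetting -----------------------------------------------------
    def subset_samples(self, sample_ids: list[str]) -> "BinaryCharacterMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return BinaryCharacterMatrix(
            self.calls[idx],
            list(sample_ids),
            list(self.locus_ids),
            {s: sp for s, sp in self.species_map.items() if s in set(sample_ids)},
        )

    def drop_species(self, species: str) -> "BinaryCharacterMatrix":
        keep = [s for s in self.sample_ids if self.species_map.get(s) != species]
        if len(keep) == len(self.sample_ids):
            raise AflPhyloError(f"species {species!r} has no samples to drop")
        if not keep:
            raise AflPhyloError("dropping this species would empty the matrix")
        return self.subset_samples(keep)

    def subset_loci(self, column_idx) -> "BinaryCharacterMatrix":
        column_idx = np.asarray(column_idx, dtype=int)
        return BinaryCharacterMatrix(
            self.calls[:, column_idx],
            list(self.sample_ids),
            [self.locus_ids[j] for j in column_idx],
            dict(self.species_map),
        )

    def polymorphic_mask(self) -> np.ndarray:
        colsum = self.calls.sum(axis=0)
        return (colsum > 0) & (colsum < self.n_samples)

    def equals(self, other: "BinaryCharacterMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
            and self.species_map == other.species_map
        )
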