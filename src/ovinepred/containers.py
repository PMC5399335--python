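"""Core data containers shared across the pipeline.

``GenotypeMatrix`` is the raw substrate handed between the simulator, quality
control, relationship-matrix construction and BayesR.  ``Pedigree`` carries
parentage, breed proportions and the flock/birth-year structure that the
mixed model needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing allele count in GenotypeMatrix.calls


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with its marker map.

    Parameters
    ----------
    ids
        Individual identifiers, unique, one per row of ``calls``.
    snp_ids
        Marker identifiers, unique, one per column.
    chrom
        Chromosome label per SNP.
    pos
        Base-pair position per SNP.
    calls
        ``(n, m)`` int8 array of counted-allele dosages in {0, 1, 2};
        missing genotypes hold :data:`MISSING`.
    counted_allele
        Label of the allele whose dosage is stored (PLINK "A1" convention).
    call_quality
        Optional ``(n, m)`` per-genotype quality score in [0, 1]
        (the array channel a GenCal-style score would occupy).
    """

    ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    counted_allele: str = "A"
    call_quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.ascontiguousarray(self.calls, dtype=np.int8)
        if self.calls.shape != (self.ids.size, self.snp_ids.size):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.ids.size} ids x {self.snp_ids.size} snp_ids"
            )
        if self.chrom.size != self.snp_ids.size or self.pos.size != self.snp_ids.size:
            raise ValueError("chrom/pos must have one entry per SNP")
        if len(set(self.ids)) != self.ids.size:
            raise ValueError("individual ids are not unique")
        if len(set(self.snp_ids)) != self.snp_ids.size:
            raise ValueError("snp_ids are not unique")
        valid = (self.calls >= 0) & (self.calls <= 2) | (self.calls == MISSING)
        if not valid.all():
            raise ValueError("calls must be 0/1/2 or the missing sentinel")
        if self.call_quality is not None:
            self.call_quality = np.asarray(self.call_quality, dtype=np.float64)
            if self.call_quality.shape != self.calls.shape:
                raise ValueError("call_quality shape must match calls")

    @property
    def n_individuals(self) -> int:
        return self.ids.size

    @property
    def n_snps(self) -> int:
        return self.snp_ids.size

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def dosage(self, dtype=np.float64) -> np.ndarray:
        """Calls as float with missing entries as NaN."""
        d = self.calls.astype(dtype)
        d[self.calls == MISSING] = np.nan
        return d

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted allele per SNP (missing skipped)."""
        d = self.dosage()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            ids=self.ids,
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            calls=self.calls[:, index],
            counted_allele=self.counted_allele,
            call_quality=None if self.call_quality is None else self.call_quality[:, index],
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            ids=self.ids[index],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            calls=self.calls[index, :],
            counted_allele=self.counted_allele,
            call_quality=None if self.call_quality is None else self.call_quality[index, :],
        )

    def loc_individuals(self, wanted_ids) -> "GenotypeMatrix":
        """Rows for ``wanted_ids`` in the requested order."""
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            idx = np.array([lookup[w] for w in wanted_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in genotype matrix") from exc
        return self.subset_individuals(idx)


@dataclass
class Pedigree:
    """Pedigree with breed proportions and management structure.

    ``table`` has one row per animal with columns ``id``, ``sire``, ``dam``
    (empty string for unknown), one ``breed_<label>`` fraction column per
    breed (rows sum to 1), ``flock``, ``birth_year`` and ``role`` (one of
    ``founder``/``reference``/``validation_sire``/``other``).  Rows are
    topologically ordered: parents precede offspring.
    """

    table: pd.DataFrame
    breeds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        required = {"id", "sire", "dam", "flock", "birth_year"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        if "role" not in t.columns:
            t = t.assign(role="other")
            self.table = t
        if not self.breeds:
            self.breeds = [c[len("breed_"):] for c in t.columns if c.startswith("breed_")]
        if t["id"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")
        fr = self.breed_fractions()
        if fr.size and (fr.min() < -1e-12 or np.abs(fr.sum(axis=1) - 1).max() > 1e-9):
            raise ValueError("breed fractions must be nonnegative and sum to 1")
        self._check_order()

    def _check_order(self) -> None:
        seen: set = set()
        for _, row in self.table.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {row['id']!r} does not precede it "
                        "(pedigree must be topologically ordered)"
                    )
            seen.add(row["id"])

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy(dtype=object)

    def breed_fractions(self) -> np.ndarray:
        cols = [f"breed_{b}" for b in self.breeds]
        return self.table[cols].to_numpy(dtype=np.float64)

    def rows_for(self, wanted_ids) -> pd.DataFrame:
        sub = self.table.set_index("id").loc[list(wanted_ids)].reset_index()
        return sub
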