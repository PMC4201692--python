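"""Core genotype containers.

Genotype calls are stored as ``int8`` codes counting copies of the B allele:

====== =========== ==========
code   name        dosage
====== =========== ==========
0      HOM_A       0
1      HET         1
2      HOM_B       2
-1     NO_CALL     undefined
====== =========== ==========

The dosage mapping is a bijection on called genotypes; NO_CALL carries no
dosage.  Loci live on cattle autosomes 1..29 or the X chromosome ("30" is
accepted on input as an alias for X and always stored as "X").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
NO_CALL: int = -1

CALL_NAMES = {HOM_A: "AA", HET: "AB", HOM_B: "BB", NO_CALL: "--"}

X_CHROM = "X"
MAX_AUTOSOME = 29
ALLOWED_CHROMS = frozenset(str(i) for i in range(1, MAX_AUTOSOME + 1)) | {X_CHROM}

MALE = "M"
FEMALE = "F"
SEX_UNKNOWN = "U"
UNKNOWN_PARENT = "0"

LOCUS_COLUMNS = ["locus_id", "chromosome", "position_bp", "allele_a", "allele_b"]


def normalize_chrom(label) -> str:
    """Map a chromosome label to canonical form ("30" -> "X")."""
    s = str(label).strip()
    if s in ("30", "x", "X"):
        return X_CHROM
    return s


def make_locus_table(
    locus_ids,
    chromosomes,
    positions_bp,
    allele_a="A",
    allele_b="B",
    genetic_pos_cM=None,
) -> pd.DataFrame:
    """Assemble and validate a locus map table."""
    n = len(locus_ids)
    df = pd.DataFrame(
        {
            "locus_id": [str(x) for x in locus_ids],
            "chromosome": [normalize_chrom(c) for c in np.broadcast_to(np.asarray(chromosomes, dtype=object), (n,))],
            "position_bp": np.asarray(positions_bp, dtype=np.int64),
            "allele_a": np.broadcast_to(np.asarray(allele_a, dtype=object), (n,)),
            "allele_b": np.broadcast_to(np.asarray(allele_b, dtype=object), (n,)),
        }
    )
    if genetic_pos_cM is not None:
        df["genetic_pos_cM"] = np.asarray(genetic_pos_cM, dtype=float)
    validate_locus_table(df)
    return df


def validate_locus_table(loci: pd.DataFrame) -> None:
    for col in LOCUS_COLUMNS:
        if col not in loci.columns:
            raise ValueError(f"locus table missing column {col!r}")
    if loci["locus_id"].duplicated().any():
        dup = loci.loc[loci["locus_id"].duplicated(), "locus_id"].iloc[0]
        raise ValueError(f"duplicate locus_id {dup!r}")
    bad = set(loci["chromosome"]) - ALLOWED_CHROMS
    if bad:
        raise ValueError(f"chromosome labels outside 1..{MAX_AUTOSOME}/X: {sorted(bad)!r}")
    if (loci["position_bp"] <= 0).any():
        raise ValueError("positions must be strictly positive (1-based)")
    if "genetic_pos_cM" in loci.columns and (np.asarray(loci["genetic_pos_cM"]) < 0).any():
        raise ValueError("genetic positions must be nonnegative")


@dataclass
class GenotypeMatrix:
    """A samples x loci grid of genotype calls with its locus map.

    Parameters
    ----------
    sample_ids
        Ordered unique sample identifiers.
    loci
        Locus map with columns ``locus_id, chromosome, position_bp,
        allele_a, allele_b`` (optionally ``genetic_pos_cM``).
    calls
        ``int8`` array of shape (n_samples, n_loci) with values in
        {-1, 0, 1, 2}.
    quality
        Optional per-call quality score in [0, 1] (NaN where absent).
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    calls: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        validate_locus_table(self.loci)
        self.loci = self.loci.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        valid = np.isin(self.calls, (NO_CALL, HOM_A, HET, HOM_B))
        if not valid.all():
            raise ValueError("calls contain codes outside {-1, 0, 1, 2}")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape != self.calls.shape:
                raise ValueError("quality shape does not match calls")
            finite = np.isfinite(self.quality)
            if ((self.quality[finite] < 0) | (self.quality[finite] > 1)).any():
                raise ValueError("quality scores must lie in [0, 1]")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def chromosomes(self) -> np.ndarray:
        return self.loci["chromosome"].to_numpy()

    @property
    def x_mask(self) -> np.ndarray:
        return self.chromosomes == X_CHROM

    @property
    def autosomal_mask(self) -> np.ndarray:
        return ~self.x_mask

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(str(sample_id))
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    # -- views -------------------------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.calls != NO_CALL

    def dosage(self) -> np.ndarray:
        """Allele-B dosage as float, NaN at NO_CALL."""
        d = self.calls.astype(float)
        d[self.calls == NO_CALL] = np.nan
        return d

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.loci.copy(),
            self.calls[idx].copy(),
            None if self.quality is None else self.quality[idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.loci.copy(),
            self.calls.copy(),
            None if self.quality is None else self.quality.copy(),
        )

    def equals(self, other: "GenotypeMatrix", check_quality: bool = False) -> bool:
        if self.sample_ids != other.sample_ids:
            return False
        a = self.loci[LOCUS_COLUMNS].reset_index(drop=True)
        b = other.loci[LOCUS_COLUMNS].reset_index(drop=True)
        if not a.equals(b):
            return False
        if not np.array_equal(self.calls, other.calls):
            return False
        if check_quality:
            if (self.quality is None) != (other.quality is None):
                return False
            if self.quality is not None and not np.allclose(
                self.quality, other.quality, atol=1e-4, equal_nan=True
            ):
                return False
        return True

    def same_loci(self, other: "GenotypeMatrix") -> bool:
        return list(self.loci["locus_id"]) == list(other.loci["locus_id"])


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual's pedigree link (sire/dam "0" = unknown)."""

    individual_id: str
    sire_id: str = UNKNOWN_PARENT
    dam_id: str = UNKNOWN_PARENT
    sex: str = SEX_UNKNOWN

    def __post_init__(self):
        if self.sex not in (MALE, FEMALE, SEX_UNKNOWN):
            raise ValueError(f"sex must be one of M/F/U, got {self.sex!r}")


class Pedigree:
    """A set of pedigree records with parent-existence and acyclicity checks."""

    def __init__(self, records: list[PedigreeRecord]):
        self.records = list(records)
        ids = [r.individual_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual_id in pedigree")
        self._by_id = {r.individual_id: r for r in self.records}
        for r in self.records:
            for pid in (r.sire_id, r.dam_id):
                if pid != UNKNOWN_PARENT and pid not in self._by_id:
                    raise ValueError(
                        f"parent {pid!r} of {r.individual_id!r} not in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 2:
                return
            if state.get(iid) == 1:
                raise ValueError(f"pedigree cycle involving {iid!r}")
            state[iid] = 1
            rec = self._by_id[iid]
            for pid in (rec.sire_id, rec.dam_id):
                if pid != UNKNOWN_PARENT:
                    visit(pid, stack + [iid])
            state[iid] = 2

        for r in self.records:
            visit(r.individual_id, [])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def get(self, iid: str) -> PedigreeRecord:
        return self._by_id[iid]

    def parents(self, iid: str) -> tuple[str, str]:
        r = self._by_id[iid]
        return r.sire_id, r.dam_id

    def kinship(self, a: str, b: str, _memo=None) -> float:
        """Coefficient of kinship f(a, b) by tabular recursion.

        Unknown parents are treated as unrelated, non-inbred founders.
        """
        if _memo is None:
            _memo = {}
        key = (a, b) if a <= b else (b, a)
        if key in _memo:
            return _memo[key]
        if a == UNKNOWN_PARENT or b == UNKNOWN_PARENT:
            return 0.0
        if a == b:
            sa, da = self.parents(a)
            val = 0.5 * (1.0 + self.kinship(sa, da, _memo))
        else:
            # recurse on the individual appearing later in a topological order;
            # here we use "has known parents" as a proxy, valid for the
            # generational pedigrees this package produces
            ra, rb = self._by_id[a], self._by_id[b]
            if ra.sire_id == UNKNOWN_PARENT and ra.dam_id == UNKNOWN_PARENT:
                a, b = b, a
                ra, rb = rb, ra
            sa, da = ra.sire_id, ra.dam_id
            if sa == UNKNOWN_PARENT and da == UNKNOWN_PARENT:
                val = 0.0
            else:
                val = 0.5 * (self.kinship(sa, b, _memo) + self.kinship(da, b, _memo))
        _memo[key] = val
        return val

    def inbreeding(self, iid: str) -> float:
        """Wright's pedigree inbreeding coefficient F = f(sire, dam)."""
        sire, dam = self.parents(iid)
        return self.kinship(sire, dam)
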