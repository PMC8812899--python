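"""Reading, validation, writing, and harmonization of GWAS summary statistics.

Summary statistics are exchanged as tab-delimited text with a header; the
canonical column names are ``SNP, CHR, BP, EA, NEA, EAF, BETA, SE, P, N``
(effect allele EA, non-effect allele NEA, effect-allele frequency EAF).
Other dialects are mapped onto these names via a ``dialect`` dictionary.

Pairwise linkage disequilibrium is carried as a signed correlation matrix
(r, not r^2): the sign matters wherever the matrix enters a quadratic form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N")
REQUIRED_COLUMNS = ("SNP", "EA", "NEA", "EAF", "BETA", "SE", "P")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryStatsFormatError(ValueError):
    """Raised when a summary-statistics file violates the expected format."""


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele.upper())


def is_palindromic(a1: str, a2: str) -> bool:
    """True when the allele pair is strand-ambiguous (A/T or C/G)."""
    return _complement(a1) == a2.upper()


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with a trait.

    ``beta`` is the per-effect-allele change in the trait, in whatever units
    the GWAS analysed (mm Hg for blood pressure, SD for a serum protein,
    log-odds for a case-control trait).  ``chrom``/``pos``/``n`` may be
    absent when the source table does not print them.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.effect_allele.upper() == self.other_allele.upper():
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.snp_id}: pvalue {self.pvalue} outside (0, 1]")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be 1-based (>= 1)")
        if self.n is not None and self.n < 1:
            raise ValueError(f"{self.snp_id}: n must be >= 1")
        self._check_p_consistency()

    def _check_p_consistency(self) -> None:
        # Published tables round beta/se heavily; warn (never reject) when the
        # reported p is more than one order of magnitude off the recomputed one.
        z = abs(self.beta) / self.se
        with np.errstate(divide="ignore"):
            logp_recomputed = (stats.norm.logsf(z) + math.log(2.0)) / math.log(10.0)
        logp_reported = math.log10(self.pvalue)
        if abs(logp_reported - logp_recomputed) > 1.0 and z > 0:
            logger.warning(
                "%s: reported p=%.3g inconsistent with |beta/se|=%.2f "
                "(recomputed p=1e%.1f)",
                self.snp_id,
                self.pvalue,
                z,
                logp_recomputed,
            )

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class SummaryStatsTable:
    """Ordered collection of :class:`VariantAssociation` for one trait."""

    records: list[VariantAssociation]
    trait_label: str = ""
    trait_units: str = ""

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_ids in table: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, snp_id: str) -> VariantAssociation | None:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        return None

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.snp_id,
                "CHR": r.chrom,
                "BP": r.pos,
                "EA": r.effect_allele,
                "NEA": r.other_allele,
                "EAF": r.eaf,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pvalue,
                "N": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome associations aligned to one effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (self.se_exposure > 0 and self.se_outcome > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


@dataclass(frozen=True)
class DroppedVariant:
    snp_id: str
    reason: str  # missing_in_outcome | palindromic_ambiguous | incompatible_alleles


@dataclass
class HarmonizationResult:
    pairs: list[HarmonizedPair]
    dropped: list[DroppedVariant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str = "",
    trait_units: str = "",
) -> SummaryStatsTable:
    """Read a tab-delimited summary-statistics file.

    ``dialect`` maps canonical column names to the file's column names,
    e.g. ``{"SNP": "rsid", "P": "pval"}``; unmapped names are taken as-is.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    dialect = dict(dialect or {})
    rename = {v: k for k, v in dialect.items()}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )

    records: list[VariantAssociation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        d = row._asdict()
        try:
            records.append(
                VariantAssociation(
                    snp_id=str(d["SNP"]),
                    chrom=None if _blank(d.get("CHR")) else str(d["CHR"]),
                    pos=None if _blank(d.get("BP")) else int(float(d["BP"])),
                    effect_allele=str(d["EA"]).upper(),
                    other_allele=str(d["NEA"]).upper(),
                    eaf=float(d["EAF"]),
                    beta=float(d["BETA"]),
                    se=float(d["SE"]),
                    pvalue=float(d["P"]),
                    n=None if _blank(d.get("N")) else float(d["N"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SummaryStatsFormatError(f"{path}, line {i}: {exc}") from exc
    return SummaryStatsTable(records, trait_label=trait_label, trait_units=trait_units)


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v) in ("", "nan", "NA", "None")


def write_summary_stats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write a table in the canonical tab-delimited layout (lossless round-trip)."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def harmonize_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_band: float = 0.08,
) -> HarmonizationResult:
    """Align outcome associations to the exposure's effect alleles.

    For each exposure SNP found in the outcome table, the outcome record is
    aligned to the exposure effect allele: identical allele labels pass
    through; swapped labels flip the outcome beta sign and complement its
    frequency; non-palindromic pairs are additionally matched after strand
    complementation.  Palindromic SNPs (A/T or C/G) whose *outcome*
    effect-allele frequency lies within ``0.5 +/- palindrome_eaf_band`` are
    dropped as strand-ambiguous.  Nothing is dropped silently: every removed
    SNP is returned with a reason.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("both exposure and outcome tables must be non-empty")
    if not (0 <= palindrome_eaf_band < 0.5):
        raise ValueError("palindrome_eaf_band must be in [0, 0.5)")

    pairs: list[HarmonizedPair] = []
    dropped: list[DroppedVariant] = []
    for exp in exposure:
        out = outcome.get(exp.snp_id)
        if out is None:
            dropped.append(DroppedVariant(exp.snp_id, "missing_in_outcome"))
            continue

        palindromic = is_palindromic(exp.effect_allele, exp.other_allele)
        if palindromic and abs(out.eaf - 0.5) <= palindrome_eaf_band:
            dropped.append(DroppedVariant(exp.snp_id, "palindromic_ambiguous"))
            continue

        alignment = _align_alleles(exp, out, allow_strand_flip=not palindromic)
        if alignment is None:
            dropped.append(DroppedVariant(exp.snp_id, "incompatible_alleles"))
            continue
        beta_out, eaf_out, flipped = alignment
        pairs.append(
            HarmonizedPair(
                snp_id=exp.snp_id,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                eaf_exposure=exp.eaf,
                eaf_outcome=eaf_out,
                flipped=flipped,
            )
        )
    return HarmonizationResult(pairs=pairs, dropped=dropped)


def _align_alleles(
    exp: VariantAssociation,
    out: VariantAssociation,
    allow_strand_flip: bool,
) -> tuple[float, float, bool] | None:
    """Return (beta_outcome, eaf_outcome, flipped) aligned to exp's effect allele."""
    e_ea, e_oa = exp.effect_allele.upper(), exp.other_allele.upper()
    candidates = [(out.effect_allele.upper(), out.other_allele.upper(), False)]
    if allow_strand_flip:
        candidates.append(
            (_complement(out.effect_allele), _complement(out.other_allele), True)
        )
    for o_ea, o_oa, _strand in candidates:
        if (o_ea, o_oa) == (e_ea, e_oa):
            return out.beta, out.eaf, False
        if (o_ea, o_oa) == (e_oa, e_ea):
            return -out.beta, 1.0 - out.eaf, True
    return None


@dataclass
class LDMatrix:
    """Signed pairwise LD correlations over an ordered SNP panel."""

    snp_ids: list[str]
    r: np.ndarray

    PSD_TOL = 1e-8

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({m}, {m})")
        if not np.allclose(self.r, self.r.T, atol=1e-6):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-9):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self.r = (self.r + self.r.T) / 2.0
        eigmin = float(np.linalg.eigvalsh(self.r).min())
        if eigmin < -self.PSD_TOL:
            logger.warning("LD matrix min eigenvalue %.3g < 0; clipping to PSD", eigmin)
            self.r = _clip_to_psd(self.r)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def r2(self) -> np.ndarray:
        return self.r**2

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))


def _clip_to_psd(a: np.ndarray) -> np.ndarray:
    """Eigenvalue-clip to the PSD cone and restore the unit diagonal."""
    w, v = np.linalg.eigh(a)
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def read_ld_matrix(path: str | Path, snp_ids: Sequence[str]) -> LDMatrix:
    """Read LD as a square labelled matrix or a long-format (id1, id2, r) list.

    The result is reordered to ``snp_ids``.  In long format, pairs not listed
    default to r = 0 (with a logged warning) — appropriate for post-pruning
    panels that are weakly correlated by construction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    snp_ids = list(snp_ids)

    if df.shape[1] == 3 and not set(snp_ids).issubset(df.columns):
        return _ld_from_long(df, snp_ids, path)
    return _ld_from_square(path, snp_ids)


def _ld_from_long(df: pd.DataFrame, snp_ids: list[str], path: Path) -> LDMatrix:
    id1, id2, rcol = df.columns
    known = set(df[id1].astype(str)) | set(df[id2].astype(str))
    missing = [s for s in snp_ids if s not in known]
    if missing:
        raise ValueError(f"{path}: snp_ids absent from LD file: {missing}")
    index = {s: i for i, s in enumerate(snp_ids)}
    m = len(snp_ids)
    r = np.eye(m)
    seen = np.eye(m, dtype=bool)
    for a, b, val in zip(df[id1].astype(str), df[id2].astype(str), df[rcol].astype(float)):
        if a in index and b in index:
            i, j = index[a], index[b]
            r[i, j] = r[j, i] = val
            seen[i, j] = seen[j, i] = True
    n_missing = int((~seen).sum() // 2)
    if n_missing:
        logger.warning("%s: %d LD pairs absent; defaulting to r=0", path, n_missing)
    return LDMatrix(snp_ids, r)


def _ld_from_square(path: Path, snp_ids: list[str]) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = [s for s in snp_ids if s not in df.index or s not in df.columns]
    if missing:
        raise ValueError(f"{path}: snp_ids absent from LD file: {missing}")
    sub = df.loc[snp_ids, snp_ids].to_numpy(dtype=float)
    if not np.allclose(sub, sub.T, atol=1e-6):
        raise ValueError(f"{path}: square LD matrix has asymmetric entries (>1e-6)")
    return LDMatrix(snp_ids, sub)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")
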