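"""Readers and writers for the external file formats the toolkit touches.

All tabular formats are plain whitespace/TSV text. Readers validate
aggressively and raise :class:`FormatError` naming the offending location;
there is no silent coercion. Writers and readers round-trip exactly for
dosage, phenotype and prior-count tables.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MarkerMap",
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_dosage_table",
    "write_dosage_table",
    "read_marker_map",
    "write_marker_map",
    "read_vcf_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_prior_counts",
    "write_prior_counts",
    "write_results",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending location."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Genomic coordinates of the markers backing a genotype matrix.

    Parameters
    ----------
    marker_id
        Unique marker identifiers, in matrix column order.
    chrom
        Chromosome label per marker.
    pos_bp
        1-based physical position in base pairs.

    Rows are stored in matrix column order, i.e. ``col_index`` of marker
    ``i`` is ``i``. Within each chromosome positions must be strictly
    increasing, and each chromosome's markers must be contiguous.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray

    def __post_init__(self):
        mid = np.asarray(self.marker_id, dtype=object)
        ch = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos_bp, dtype=np.int64)
        if not (len(mid) == len(ch) == len(pos)):
            raise ValueError("marker map fields have unequal lengths")
        if len(np.unique(mid)) != len(mid):
            raise FormatError("duplicate marker_id in marker map")
        if np.any(pos < 1):
            raise FormatError("pos_bp must be positive (1-based)")
        # chromosome blocks contiguous, positions increasing within a block
        seen = {}
        prev = None
        for i, c in enumerate(ch):
            if c != prev:
                if c in seen:
                    raise FormatError(f"chromosome {c!r} is not contiguous in map")
                seen[c] = True
                prev = c
            elif pos[i] <= pos[i - 1]:
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c!r} "
                    f"at marker {mid[i]!r}"
                )
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chrom", ch)
        object.__setattr__(self, "pos_bp", pos)

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def subset(self, idx) -> "MarkerMap":
        """Return the map restricted to column indices ``idx`` (map order kept)."""
        idx = np.asarray(idx)
        return MarkerMap(self.marker_id[idx], self.chrom[idx], self.pos_bp[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "col_index": np.arange(len(self)),
            }
        )

    @staticmethod
    def default(m: int) -> "MarkerMap":
        """Synthesized map: single chromosome "1", positions 1..m."""
        return MarkerMap(
            np.array([f"m{j + 1}" for j in range(m)], dtype=object),
            np.array(["1"] * m, dtype=object),
            np.arange(1, m + 1, dtype=np.int64),
        )


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-dosage matrix with its marker map.

    ``X[i, j]`` counts copies of the second (ALT) allele carried by sample
    ``i`` at marker ``j`` and is 0, 1 or 2, except where missing genotypes
    were mean-imputed (then ``imputed`` is True and entries may be the
    fractional column mean 2*p_j).
    """

    X: np.ndarray
    sample_ids: np.ndarray
    map: MarkerMap
    imputed: bool = False

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x markers)")
        if self.X.shape[0] != len(self.sample_ids):
            raise ValueError("X rows do not match sample_ids")
        if self.X.shape[1] != len(self.map):
            raise ValueError("X columns do not match marker map")
        if len(np.unique(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample_id")
        if not self.imputed:
            bad = ~np.isin(self.X, (0.0, 1.0, 2.0))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(
                    f"dosage out of {{0,1,2}} at sample {self.sample_ids[i]!r}, "
                    f"marker {self.map.marker_id[j]!r}"
                )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.X[:, idx], self.sample_ids, self.map.subset(idx), self.imputed
        )


@dataclass
class PhenotypeTable:
    """One record per (sample, trait): phenotype value and its reliability.

    Reliability is the squared accuracy r_y^2 of the pseudo-phenotype
    (daughter trait deviation or deregressed proof) and must lie in (0, 1].
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "trait", "value", "reliability")

    def __post_init__(self):
        df = self.df
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns {missing}")
        df = df.copy()
        df["value"] = df["value"].astype(float)
        df["reliability"] = df["reliability"].astype(float)
        bad = df[(df["reliability"] <= 0) | (df["reliability"] > 1)]
        if len(bad):
            r = bad.iloc[0]
            raise FormatError(
                f"reliability {r['reliability']} outside (0,1] for sample "
                f"{r['sample_id']!r}, trait {r['trait']!r}"
            )
        dup = df.duplicated(subset=["sample_id", "trait"])
        if dup.any():
            r = df[dup].iloc[0]
            raise FormatError(
                f"duplicate record for sample {r['sample_id']!r}, trait {r['trait']!r}"
            )
        self.df = df.reset_index(drop=True)

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.df[self.df["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no records for trait {trait!r}")
        return sub.reset_index(drop=True)

    def values_for(self, sample_ids, trait: str) -> np.ndarray:
        """Phenotype values aligned to ``sample_ids`` order."""
        sub = self.for_trait(trait).set_index("sample_id")
        missing = [s for s in sample_ids if s not in sub.index]
        if missing:
            raise KeyError(f"no phenotype for samples {missing[:5]}")
        return sub.loc[list(sample_ids), "value"].to_numpy(dtype=float)

    def mean_reliability(self, trait: str) -> float:
        return float(self.for_trait(trait)["reliability"].mean())


# ---------------------------------------------------------------------------
# Dosage tables
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"NA", "na", ".", "-9"}


def read_dosage_table(
    path, map_path=None, mean_impute: bool = False
) -> GenotypeMatrix:
    """Read a whitespace-delimited dosage table.

    Layout: header row of marker ids; each following row is a sample id and
    one 0/1/2 dosage per marker. Missing cells (``NA`` or ``.``) are an
    error unless ``mean_impute`` is set, in which case they are replaced by
    the marker mean dosage 2*p_j and the result is flagged as imputed.
    A companion map file (``map_path``) supplies coordinates; without one,
    positions are synthesized as chromosome "1", 1 bp apart.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise FormatError(f"{path}: empty file")
        marker_ids = header
        m = len(marker_ids)
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        any_missing = False
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != m + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {m + 1} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            row = np.empty(m, dtype=np.float64)
            for j, tok in enumerate(parts[1:]):
                if tok in _MISSING_TOKENS:
                    if not mean_impute:
                        raise FormatError(
                            f"{path}:{lineno}: missing genotype for sample "
                            f"{parts[0]!r}, marker {marker_ids[j]!r} "
                            "(pass mean_impute=True to fill with 2p)"
                        )
                    row[j] = np.nan
                    any_missing = True
                elif tok in ("0", "1", "2"):
                    row[j] = float(tok)
                else:
                    raise FormatError(
                        f"{path}:{lineno}: invalid dosage {tok!r} for sample "
                        f"{parts[0]!r}, marker {marker_ids[j]!r}"
                    )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    X = np.vstack(rows)
    if any_missing:
        col_mean = np.nanmean(X, axis=0)
        nan_idx = np.where(np.isnan(X))
        X[nan_idx] = col_mean[nan_idx[1]]
    if map_path is not None:
        mmap = read_marker_map(map_path)
        if list(mmap.marker_id) != marker_ids:
            raise FormatError(
                f"{map_path}: marker ids do not match dosage table header"
            )
    else:
        mmap = MarkerMap(
            np.array(marker_ids, dtype=object),
            np.array(["1"] * m, dtype=object),
            np.arange(1, m + 1, dtype=np.int64),
        )
    return GenotypeMatrix(X, np.array(sample_ids, dtype=object), mmap,
                          imputed=any_missing)


def write_dosage_table(G: GenotypeMatrix, path) -> None:
    """Write a dosage table readable by :func:`read_dosage_table`."""
    with open(path, "w") as fh:
        fh.write(" ".join(str(x) for x in G.map.marker_id) + "\n")
        for i, sid in enumerate(G.sample_ids):
            if G.imputed:
                cells = " ".join(format(v, ".10g") for v in G.X[i])
            else:
                cells = " ".join(str(int(v)) for v in G.X[i])
            fh.write(f"{sid} {cells}\n")


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep=r"\s+", dtype={"marker_id": str, "chrom": str})
    for col in ("marker_id", "chrom", "pos_bp"):
        if col not in df.columns:
            raise FormatError(f"{path}: map file missing column {col!r}")
    if "col_index" in df.columns:
        df = df.sort_values("col_index")
    return MarkerMap(
        df["marker_id"].to_numpy(dtype=object),
        df["chrom"].to_numpy(dtype=object),
        df["pos_bp"].to_numpy(dtype=np.int64),
    )


def write_marker_map(mmap: MarkerMap, path) -> None:
    mmap.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_genotypes(
    path, skip_multiallelic: bool = False, mean_impute: bool = False
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into ALT-allele dosages.

    Dosage is the number of ALT alleles in the GT field; phase is ignored.
    Multiallelic records raise unless ``skip_multiallelic``. Missing GTs
    raise unless ``mean_impute`` (then they become the marker mean 2p_j).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = np.array(vcf.samples, dtype=object)
    marker_ids, chroms, poss, cols = [], [], [], []
    any_missing = False
    for idx, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if skip_multiallelic:
                continue
            raise FormatError(
                f"{path}: multiallelic record at {var.CHROM}:{var.POS} "
                "(set skip_multiallelic to drop such records)"
            )
        gt = np.asarray(var.gt_types, dtype=np.float64)  # 0,1,2; 3 = missing
        miss = gt == 3
        if miss.any():
            if not mean_impute:
                i = int(np.argmax(miss))
                raise FormatError(
                    f"{path}: missing genotype for sample {sample_ids[i]!r} at "
                    f"{var.CHROM}:{var.POS} (pass mean_impute=True)"
                )
            gt[miss] = np.nan
            any_missing = True
        marker_ids.append(var.ID if var.ID not in (None, ".") else
                          f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        cols.append(gt)
    if not cols:
        raise FormatError(f"{path}: no biallelic records")
    X = np.column_stack(cols)
    if any_missing:
        col_mean = np.nanmean(X, axis=0)
        nan_idx = np.where(np.isnan(X))
        X[nan_idx] = col_mean[nan_idx[1]]
    mmap = MarkerMap(
        np.array(marker_ids, dtype=object),
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
    )
    return GenotypeMatrix(X, sample_ids, mmap, imputed=any_missing)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path) -> PhenotypeTable:
    """Read a TSV with columns sample_id, trait, value, reliability."""
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype={"sample_id": str, "trait": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    try:
        return PhenotypeTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dirichlet prior-count tables
# ---------------------------------------------------------------------------

_PRIOR_COLS = [
    "segment_index", "chrom", "start_bp", "end_bp",
    "alpha0", "alpha1", "alpha2", "alpha3",
]


def read_prior_counts(path):
    """Read a per-segment Dirichlet parameter table.

    Returns a :class:`bayesrs.prior_transfer.DirichletPriorTable`. All four
    alpha columns must be strictly positive and segment indices must run
    0..S-1 without gaps.
    """
    from .prior_transfer import DirichletPriorTable

    df = pd.read_csv(path, sep=r"\s+", dtype={"chrom": str})
    missing = [c for c in _PRIOR_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: prior table missing columns {missing}")
    seg = df["segment_index"].to_numpy()
    if not np.array_equal(np.sort(seg), np.arange(len(seg))):
        raise FormatError(f"{path}: segment_index must be 0..{len(seg) - 1} without gaps")
    df = df.sort_values("segment_index").reset_index(drop=True)
    alphas = df[["alpha0", "alpha1", "alpha2", "alpha3"]].to_numpy(dtype=float)
    if np.any(alphas <= 0):
        i, k = np.argwhere(alphas <= 0)[0]
        raise FormatError(
            f"{path}: alpha{k} = {alphas[i, k]} in segment {i} must be > 0"
        )
    coords = df[["chrom", "start_bp", "end_bp"]].copy()
    return DirichletPriorTable(alphas=alphas, coords=coords, scale=1.0,
                               provenance={"source": str(path)})


def write_prior_counts(prior, path) -> None:
    """Write a DirichletPriorTable as the TSV read by :func:`read_prior_counts`."""
    alphas = np.asarray(prior.alphas, dtype=float)
    df = prior.coords.copy().reset_index(drop=True)
    df.insert(0, "segment_index", np.arange(len(df)))
    for k in range(4):
        df[f"alpha{k}"] = [repr(float(a)) for a in alphas[:, k]]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def write_results(summary, prefix) -> dict[str, Path]:
    """Write a finished chain's posterior summaries.

    Emits ``<prefix>.effects.tsv`` (per-marker posterior-mean effect and
    component occupancy), ``<prefix>.segvar.tsv`` (per-segment posterior-mean
    variance and proportion of summed segment variance) and
    ``<prefix>.meta.txt`` (seed, chain settings, sigma_g2, frequency
    provenance). Returns the paths written. Output is deterministic: a rerun
    with the same seed and inputs reproduces the files byte-for-byte.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mmap = summary.map
    paths = {}

    eff = prefix.with_suffix(prefix.suffix + ".effects.tsv")
    with open(eff, "w") as fh:
        fh.write("marker_id\tchrom\tpos_bp\teffect\tocc0\tocc1\tocc2\tocc3\n")
        for j in range(len(mmap)):
            occ = "\t".join(format(v, ".10g") for v in summary.occupancy[j])
            fh.write(
                f"{mmap.marker_id[j]}\t{mmap.chrom[j]}\t{mmap.pos_bp[j]}\t"
                f"{format(summary.g_mean[j], '.10g')}\t{occ}\n"
            )
    paths["effects"] = eff

    seg = prefix.with_suffix(prefix.suffix + ".segvar.tsv")
    summary.segment_variances.to_frame(summary.report_partition).to_csv(
        seg, sep="\t", index=False, float_format="%.10g"
    )
    paths["segvar"] = seg

    meta = prefix.with_suffix(prefix.suffix + ".meta.txt")
    cfg = summary.config
    with open(meta, "w") as fh:
        fh.write(f"seed\t{cfg.seed}\n")
        fh.write(f"n_iter\t{cfg.n_iter}\n")
        fh.write(f"burn_in\t{cfg.burn_in}\n")
        fh.write(f"thin\t{cfg.thin}\n")
        fh.write(f"include_polygenic\t{cfg.include_polygenic}\n")
        fh.write(f"sigma_g2\t{format(summary.sigma_g2, '.12g')}\n")
        fh.write(f"sigma_e2_mean\t{format(summary.sigma_e2_mean, '.12g')}\n")
        if summary.sigma_a2_mean is not None:
            fh.write(f"sigma_a2_mean\t{format(summary.sigma_a2_mean, '.12g')}\n")
        fh.write(f"mu_mean\t{format(summary.mu_mean, '.12g')}\n")
        fh.write(f"n_pi_segments\t{summary.pi_mean.shape[0]}\n")
        fh.write(f"frequencies\t{summary.freq_provenance}\n")
    paths["meta"] = meta
    return paths
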