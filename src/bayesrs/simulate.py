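"""Paired source/target population simulator.

Emulates the data structure cross-population prior transfer assumes: a large
source population and a small target population that share QTL positions
(with correlated effect sizes) but differ in LD strength and allele
frequencies. Haplotypes follow a first-order Markov copying model along each
chromosome — a seedable, desk-scale stand-in for real LD whose strength is
directly controllable per population, so LD-phase inconsistency between
populations can be emulated. Phenotypes are marker term + optional iid
polygenic term + Gaussian residual, with the marker term rescaled to hit the
requested variance fraction exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_prep import allele_frequencies, standardize
from .io_formats import (
    GenotypeMatrix,
    MarkerMap,
    PhenotypeTable,
    write_dosage_table,
    write_marker_map,
    write_phenotypes,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_study",
]


@dataclass(frozen=True)
class SimConfig:
    """Study design for the two-population simulation.

    The defaults define the desk-scale study: a 2,000-animal source
    population, a 400-animal target reference with 200 validation animals,
    2,000 markers on 10 chromosomes, and 20 QTL whose effects come from the
    moderate (0.001 sigma_g2) and large (0.01 sigma_g2) mixture components
    in a 3:1 ratio. Effects correlate rho_g = 0.9 across populations at
    shared QTL. Source and target differ in haplotype copying rate (LD) and
    in allele frequencies (bounded perturbation), emulating related but
    distinct breeds.
    """

    n_source: int = 2_000
    n_target: int = 400
    n_validation: int = 200
    m_markers: int = 2_000
    n_chromosomes: int = 10
    segment_size: int = 100
    n_qtl: int = 20
    qtl_spec: tuple | None = None          # ((marker_index, component), ...)
    shared_qtl: bool = True
    effect_correlation: float = 0.9        # rho_g at shared QTL
    ld_source: float = 0.7
    ld_target: float = 0.5
    maf_range: tuple = (0.05, 0.5)
    freq_divergence: float = 0.1
    h2_marker: float = 0.5
    h2_polygenic: float = 0.0
    trait: str = "sim"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_source", "n_target", "n_validation", "m_markers",
                     "n_chromosomes", "segment_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.effect_correlation <= 1):
            raise ValueError("effect_correlation must be in [0, 1]")
        for name in ("ld_source", "ld_target"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0 <= self.h2_marker < 1 and 0 <= self.h2_polygenic < 1
                and self.h2_marker + self.h2_polygenic < 1):
            raise ValueError("h2_marker + h2_polygenic must be < 1")
        if self.qtl_spec is not None:
            spec = tuple((int(j), int(c)) for j, c in self.qtl_spec)
            for j, c in spec:
                if not (0 <= j < self.m_markers):
                    raise ValueError(f"QTL marker index {j} out of range")
                if c not in (1, 2, 3):
                    raise ValueError("QTL component must be 1, 2 or 3")
            object.__setattr__(self, "qtl_spec", spec)


@dataclass
class SimTruth:
    """Ground truth: per-marker components and (scaled) effects per population."""

    marker_ids: np.ndarray
    component_source: np.ndarray
    component_target: np.ndarray
    effect_source: np.ndarray
    effect_target: np.ndarray
    polygenic: dict = field(default_factory=dict)   # population -> vector

    def __post_init__(self):
        for comp, eff in ((self.component_source, self.effect_source),
                          (self.component_target, self.effect_target)):
            if np.any((comp == 0) & (eff != 0)):
                raise ValueError("component-0 markers must have exactly zero effect")

    def qtl_indices(self, population: str = "source") -> np.ndarray:
        comp = self.component_source if population == "source" else self.component_target
        return np.flatnonzero(comp > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "component_source": self.component_source,
                "component_target": self.component_target,
                "effect_source": self.effect_source,
                "effect_target": self.effect_target,
            }
        )


@dataclass
class SimStudy:
    """All pieces of one simulated two-population study."""

    config: SimConfig
    map: MarkerMap
    source: GenotypeMatrix
    source_pheno: PhenotypeTable
    target_ref: GenotypeMatrix
    target_ref_pheno: PhenotypeTable
    target_val: GenotypeMatrix
    target_val_pheno: PhenotypeTable
    truth: SimTruth


def default_map(m: int, n_chromosomes: int, spacing_bp: int = 50_000) -> MarkerMap:
    per = int(np.ceil(m / n_chromosomes))
    chroms, poss, ids = [], [], []
    for j in range(m):
        c = j // per + 1
        chroms.append(str(c))
        poss.append((j % per) * spacing_bp + 1)
        ids.append(f"snp{j + 1:06d}")
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                     np.array(poss, dtype=np.int64))


def simulate_genotypes(n: int, mmap: MarkerMap, freqs: np.ndarray, ld: float,
                       rng: np.random.Generator, id_prefix: str = "ind") -> GenotypeMatrix:
    """Draw n individuals as sums of two Markov-copying gametes.

    Along each chromosome, a gamete's allele at marker j copies its allele
    at marker j-1 with probability ``ld``, otherwise draws fresh from
    Bernoulli(p_j); chains restart at chromosome boundaries. With equal
    adjacent frequencies this gives adjacent-allele correlation ``ld``.
    """
    m = len(mmap)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (m,):
        raise ValueError("frequency vector does not match map")
    H = np.empty((n, 2, m), dtype=np.int8)
    chrom = mmap.chrom
    for j in range(m):
        fresh = rng.random((n, 2)) < freqs[j]
        if j == 0 or chrom[j] != chrom[j - 1]:
            H[:, :, j] = fresh
        else:
            copy = rng.random((n, 2)) < ld
            H[:, :, j] = np.where(copy, H[:, :, j - 1], fresh)
    X = H.sum(axis=1).astype(np.float64)
    ids = np.array([f"{id_prefix}{i + 1:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(X, ids, mmap)


def _draw_components(cfg: SimConfig, rng: np.random.Generator, avoid=None):
    """QTL positions and components; defaults place 20 QTL, 3:1 moderate:large.

    ``avoid`` is a set of marker indices whose *segments* (of
    ``cfg.segment_size`` markers) must stay QTL-free — used by the
    disjoint-QTL mode so "disjoint" holds at the resolution the segment
    priors act on, not just marker-by-marker.
    """
    if cfg.qtl_spec is not None:
        idx = np.array([j for j, _ in cfg.qtl_spec], dtype=np.int64)
        comp = np.array([c for _, c in cfg.qtl_spec], dtype=np.int64)
        return idx, comp
    candidates = np.arange(cfg.m_markers)
    if avoid is not None and len(avoid):
        blocked_segs = {j // cfg.segment_size for j in avoid}
        candidates = candidates[
            ~np.isin(candidates // cfg.segment_size, list(blocked_segs))
        ]
        if candidates.size < cfg.n_qtl:
            raise ValueError(
                "not enough QTL-free segments to place disjoint target QTL"
            )
    idx = np.sort(rng.choice(candidates, size=cfg.n_qtl, replace=False))
    n_large = max(1, int(round(cfg.n_qtl * 0.25)))
    comp = np.full(cfg.n_qtl, 2, dtype=np.int64)
    comp[rng.choice(cfg.n_qtl, size=n_large, replace=False)] = 3
    return idx, comp


def simulate_effects(cfg: SimConfig, rng: np.random.Generator,
                     marker_ids=None, scalers=(0.0, 1e-4, 1e-3, 1e-2)) -> SimTruth:
    """Mixture-distributed raw effects for both populations.

    Source QTL effects are N(0, gamma_c) (on a nominal unit sigma_g2 scale —
    the absolute scale is set later when phenotypes are variance-targeted).
    With shared QTL, the target effect at each QTL is
    ``rho_g * g + sqrt(1 - rho_g^2) * g'`` with an independent draw g' from
    the same component; with ``shared_qtl=False`` the target gets its own
    QTL positions and components, drawn independently.
    """
    m = cfg.m_markers
    if marker_ids is None:
        marker_ids = np.array([f"snp{j + 1:06d}" for j in range(m)], dtype=object)
    scal = np.asarray(scalers)
    idx_s, comp_s = _draw_components(cfg, rng)
    component_source = np.zeros(m, dtype=np.int64)
    component_source[idx_s] = comp_s
    effect_source = np.zeros(m)
    sd_s = np.sqrt(scal[comp_s])
    effect_source[idx_s] = rng.normal(0.0, 1.0, size=len(idx_s)) * sd_s

    if cfg.shared_qtl:
        component_target = component_source.copy()
        rho = cfg.effect_correlation
        indep = rng.normal(0.0, 1.0, size=len(idx_s)) * sd_s
        effect_target = np.zeros(m)
        effect_target[idx_s] = rho * effect_source[idx_s] + np.sqrt(1 - rho**2) * indep
    else:
        idx_t, comp_t = _draw_components(cfg, rng, avoid=set(idx_s.tolist()))
        component_target = np.zeros(m, dtype=np.int64)
        component_target[idx_t] = comp_t
        effect_target = np.zeros(m)
        effect_target[idx_t] = rng.normal(0.0, 1.0, size=len(idx_t)) * np.sqrt(scal[comp_t])

    return SimTruth(
        marker_ids=np.asarray(marker_ids, dtype=object),
        component_source=component_source,
        component_target=component_target,
        effect_source=effect_source,
        effect_target=effect_target,
    )


def simulate_phenotypes(W, effects: np.ndarray, cfg: SimConfig,
                        rng: np.random.Generator, sample_ids) -> tuple[PhenotypeTable, float, np.ndarray]:
    """Phenotypes y = scaled marker term + polygenic + residual, Var(y) ~= 1.

    The marker term ``W g`` is rescaled so its empirical variance equals
    ``h2_marker`` exactly; the iid polygenic term (relationship matrix = I)
    and residual fill the remaining variance. The reliability column is set
    to ``h2_marker + h2_polygenic``, the squared accuracy of y for the total
    genetic value, which downstream anchors sigma_g2. Returns the table, the
    effect scaling factor applied, and the polygenic values.
    """
    Wm = W.W if hasattr(W, "W") else np.asarray(W, dtype=float)
    n = Wm.shape[0]
    u = Wm @ effects
    if cfg.h2_marker > 0:
        vu = u.var()
        if vu == 0:
            raise ValueError("marker term has zero variance but h2_marker > 0")
        scale = float(np.sqrt(cfg.h2_marker / vu))
    else:
        scale = 0.0
    u = u * scale
    a = rng.normal(0.0, np.sqrt(cfg.h2_polygenic), size=n) if cfg.h2_polygenic > 0 \
        else np.zeros(n)
    sigma_e = np.sqrt(1.0 - cfg.h2_marker - cfg.h2_polygenic)
    e = rng.normal(0.0, sigma_e, size=n)
    y = u + a + e
    reliability = cfg.h2_marker + cfg.h2_polygenic
    if reliability == 0:
        reliability = 1e-6  # pure-noise generator still needs a legal table
    table = PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": np.asarray(sample_ids, dtype=object),
                "trait": cfg.trait,
                "value": y,
                "reliability": reliability,
            }
        )
    )
    return table, scale, a


def simulate_study(cfg: SimConfig, out_dir=None) -> SimStudy:
    """Generate the full two-population study (optionally writing all files).

    Target reference and validation animals come from the same target
    generator (same frequencies, same LD, same effects) and get disjoint
    sample ids. When ``out_dir`` is given, writes dosage tables, the marker
    map, phenotype tables and the truth table as plain-text files.
    """
    rng = np.random.default_rng([int(cfg.seed), 0x51])
    mmap = default_map(cfg.m_markers, cfg.n_chromosomes)
    lo, hi = cfg.maf_range
    p_source = rng.uniform(lo, hi, size=cfg.m_markers)
    p_target = np.clip(
        p_source + rng.uniform(-cfg.freq_divergence, cfg.freq_divergence,
                               size=cfg.m_markers),
        lo, hi,
    )
    truth = simulate_effects(cfg, rng, marker_ids=mmap.marker_id)

    src = simulate_genotypes(cfg.n_source, mmap, p_source, cfg.ld_source, rng, "src")
    W_src = standardize(src)
    src_pheno, scale_s, a_s = simulate_phenotypes(
        W_src, truth.effect_source, cfg, rng, src.sample_ids)
    truth.effect_source = truth.effect_source * scale_s
    truth.polygenic["source"] = a_s

    n_tot = cfg.n_target + cfg.n_validation
    tgt_all = simulate_genotypes(n_tot, mmap, p_target, cfg.ld_target, rng, "tgt")
    W_tgt = standardize(tgt_all)
    tgt_pheno_all, scale_t, a_t = simulate_phenotypes(
        W_tgt, truth.effect_target, cfg, rng, tgt_all.sample_ids)
    truth.effect_target = truth.effect_target * scale_t
    truth.polygenic["target"] = a_t

    ref_ids = [f"tgt{i + 1:05d}" for i in range(cfg.n_target)]
    val_ids = [f"val{i + 1:05d}" for i in range(cfg.n_target, n_tot)]
    X = tgt_all.X
    target_ref = GenotypeMatrix(X[: cfg.n_target], np.array(ref_ids, dtype=object), mmap)
    target_val = GenotypeMatrix(X[cfg.n_target:], np.array(val_ids, dtype=object), mmap)
    df = tgt_pheno_all.df.copy()
    df["sample_id"] = np.array(ref_ids + val_ids, dtype=object)
    ref_pheno = PhenotypeTable(df.iloc[: cfg.n_target].reset_index(drop=True))
    val_pheno = PhenotypeTable(df.iloc[cfg.n_target:].reset_index(drop=True))

    study = SimStudy(
        config=cfg, map=mmap,
        source=src, source_pheno=src_pheno,
        target_ref=target_ref, target_ref_pheno=ref_pheno,
        target_val=target_val, target_val_pheno=val_pheno,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_marker_map(mmap, out / "markers.map")
        write_dosage_table(src, out / "source.dosage")
        write_phenotypes(src_pheno, out / "source.pheno.tsv")
        write_dosage_table(target_ref, out / "target_ref.dosage")
        write_phenotypes(ref_pheno, out / "target_ref.pheno.tsv")
        write_dosage_table(target_val, out / "target_val.dosage")
        write_phenotypes(val_pheno, out / "target_val.pheno.tsv")
        truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    return study
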