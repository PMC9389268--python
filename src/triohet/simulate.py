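"""Synthetic trio RNA-seq data with known ground truth.

Emulates the study design every stage of the pipeline expects: three
genotypes (female parent F, male parent M, their F1 hybrid H) with
replicated libraries, negative-binomial gene counts (variance mu + d*mu^2),
per-sample library-size variation, and gene-length variation. Each gene is
planted with one of the twelve inheritance patterns (or "conserved"), and
the generator returns a truth table so recovery can be scored.

Planted mean triples are built from a baseline mean mu and the config's
log2 effect size e: distinct expression levels are separated by a factor
2^e, with the hybrid offset one level beyond the extreme parent for the
over/under-dominant patterns (parents equal for P8/P11, separated
otherwise).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    AnnotationMap,
    CountMatrix,
    GeneModelTable,
    Role,
    SampleDesign,
    TrioHetError,
    write_annotation_gmt,
    write_count_matrix,
    write_design,
    write_gene_lengths,
)

_ROLE_PREFIX = {Role.FEMALE_PARENT: "F", Role.MALE_PARENT: "M", Role.HYBRID: "H"}

#: Relative log2 levels (F, H, M) in units of the effect size, per pattern.
_PATTERN_LEVELS: dict[str, tuple[float, float, float]] = {
    "conserved": (0, 0, 0),
    "P1": (2, 1, 0),   # F > H > M
    "P2": (0, 1, 2),   # M > H > F
    "P3": (0, 1, 1),   # H = M, F < M
    "P4": (1, 0, 0),   # H = M, F > M
    "P5": (0, 0, 1),   # H = F, F < M
    "P6": (1, 1, 0),   # H = F, F > M
    "P7": (2, 0, 1),   # H below both, F > M
    "P8": (1, 0, 1),   # H below both, F = M
    "P9": (1, 0, 2),   # H below both, F < M
    "P10": (1, 2, 0),  # H above both, F > M
    "P11": (0, 1, 0),  # H above both, F = M
    "P12": (0, 2, 1),  # H above both, F < M
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the trio count simulator.

    ``pattern_fractions`` maps pattern labels (P1..P12, conserved) to the
    fraction of genes planted with that pattern; fractions must sum to 1.
    ``effect_size`` is the log2 separation between adjacent planted
    expression levels. ``dispersion`` is the NB overdispersion d in
    variance = mu + d*mu^2 (a single value, or (shape, scale) of a gamma
    distribution when ``dispersion_gamma`` is set). Library sizes are drawn
    log-uniform within ``library_size_range`` and fixed per sample.
    """

    n_genes: int = 500
    n_reps: int = 3
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.05
    dispersion_gamma: tuple[float, float] | None = None
    pattern_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"conserved": 1.0}
    )
    effect_size: float = 2.0
    library_size_range: tuple[float, float] = (0.7, 1.4)
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.pattern_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise TrioHetError(f"pattern fractions sum to {total}, expected 1")
        unknown = set(self.pattern_fractions) - set(_PATTERN_LEVELS)
        if unknown:
            raise TrioHetError(f"unknown patterns in fractions: {sorted(unknown)}")
        if self.effect_size <= 0:
            raise TrioHetError("effect_size must be positive")
        if self.n_genes < 1 or self.n_reps < 1:
            raise TrioHetError("need >= 1 gene and >= 1 replicate")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB(mean, variance = mean + d*mean^2) samples; Poisson when d ~ 0."""
    mean = np.asarray(mean, dtype=float)
    disp = np.broadcast_to(np.asarray(disp, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = disp < 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        r = 1.0 / disp[~tiny]
        p = r / (r + mean[~tiny])
        out[~tiny] = rng.negative_binomial(r, p)
    return out


def simulate_trio(
    cfg: SimConfig,
) -> tuple[CountMatrix, list[SampleDesign], GeneModelTable, pd.DataFrame]:
    """Simulate a trio count matrix with planted inheritance patterns.

    Returns (counts, design, gene lengths, truth table). The truth table
    has one row per gene: planted_pattern, mu_F, mu_H, mu_M, dispersion.
    Identical config and seed give bitwise-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    # deterministic pattern assignment: largest remainders, then shuffle
    patterns: list[str] = []
    items = sorted(cfg.pattern_fractions.items())
    quotas = {p: f * n for p, f in items}
    base = {p: int(np.floor(q)) for p, q in quotas.items()}
    short = n - sum(base.values())
    by_rem = sorted(items, key=lambda kv: -(quotas[kv[0]] - base[kv[0]]))
    for p, _ in by_rem[:short]:
        base[p] += 1
    for p, _ in items:
        patterns.extend([p] * base[p])
    patterns = list(rng.permutation(patterns))

    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    if cfg.dispersion_gamma is not None:
        shape, scale = cfg.dispersion_gamma
        disp = rng.gamma(shape, scale, n)
    else:
        disp = np.full(n, cfg.dispersion)

    levels = np.array([_PATTERN_LEVELS[p] for p in patterns])  # (n, 3) F/H/M
    mu = baseline[:, None] * 2.0 ** (cfg.effect_size * levels)

    roles = [Role.FEMALE_PARENT, Role.HYBRID, Role.MALE_PARENT]
    design: list[SampleDesign] = []
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    lo, hi = cfg.library_size_range
    for ri, role in enumerate(roles):
        for rep in range(1, cfg.n_reps + 1):
            sf = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            columns.append(_nb_draw(rng, mu[:, ri] * sf, disp))
            sid = f"{_ROLE_PREFIX[role]}{rep}"
            sample_ids.append(sid)
            design.append(SampleDesign(sample_id=sid, role=role, replicate=rep))
    counts = CountMatrix(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(sample_ids),
        counts=np.column_stack(columns),
    )
    lengths = GeneModelTable(
        lengths={
            g: int(l)
            for g, l in zip(
                gene_ids,
                rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, n),
            )
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_pattern": patterns,
            "mu_F": mu[:, 0],
            "mu_H": mu[:, 1],
            "mu_M": mu[:, 2],
            "dispersion": disp,
        }
    )
    return counts, design, lengths, truth


def simulate_phenotype(
    f1_mean: float,
    pf_mean: float,
    pm_mean: float,
    cv: float,
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Lognormal phenotype replicates around planted genotype means.

    ``cv`` is the coefficient of variation of each replicate around its
    genotype mean; cv = 0 returns the means exactly. Columns: genotype,
    replicate, value.
    """
    for name, m in (("f1", f1_mean), ("pf", pf_mean), ("pm", pm_mean)):
        if not m > 0:
            raise TrioHetError(f"{name} mean must be positive")
    if cv < 0:
        raise TrioHetError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    rows = []
    for genotype, mean in (
        ("female_parent", pf_mean),
        ("male_parent", pm_mean),
        ("hybrid", f1_mean),
    ):
        if cv == 0:
            values = np.full(n_reps, mean)
        else:
            values = rng.lognormal(
                np.log(mean) - sigma2 / 2, np.sqrt(sigma2), n_reps
            )
        for rep, v in enumerate(values, start=1):
            rows.append({"genotype": genotype, "replicate": rep, "value": v})
    return pd.DataFrame(rows)


#: Pattern mix of the default fixture: mostly conserved background with a
#: spread of planted patterns across all three categories.
DEFAULT_FIXTURE_FRACTIONS = {
    "conserved": 0.60,
    "P1": 0.02,
    "P2": 0.02,
    "P3": 0.04,
    "P4": 0.04,
    "P5": 0.04,
    "P6": 0.04,
    "P7": 0.03,
    "P8": 0.03,
    "P9": 0.02,
    "P10": 0.05,
    "P11": 0.04,
    "P12": 0.03,
}


def default_fixture(outdir: str | Path, seed: int = 20220805) -> dict[str, Path]:
    """Write the seed-pinned tutorial/test dataset to ``outdir``.

    500 genes x 9 samples (3 genotypes x 3 replicates), NB dispersion 0.05,
    log2 effect 2, with a GMT annotation of random terms plus one term
    planted inside the above-high-parent genes (enriched by construction).
    Returns the paths written; regenerating with the same seed reproduces
    every file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(
        n_genes=500,
        n_reps=3,
        dispersion=0.05,
        effect_size=2.0,
        pattern_fractions=DEFAULT_FIXTURE_FRACTIONS,
        seed=seed,
    )
    counts, design, lengths, truth = simulate_trio(cfg)

    rng = np.random.default_rng(seed + 1)
    genes = list(counts.gene_ids)
    above_high = truth.loc[
        truth["planted_pattern"].isin(["P10", "P11", "P12"]), "gene_id"
    ].tolist()
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for i in range(20):
        tid = f"T{i:03d}"
        size = int(rng.integers(10, 40))
        terms[tid] = frozenset(rng.choice(genes, size=size, replace=False))
        names[tid] = f"random term {i}"
    planted = set(rng.choice(above_high, size=min(15, len(above_high)), replace=False))
    planted |= set(rng.choice(genes, size=5, replace=False))
    terms["T_PLANTED"] = frozenset(planted)
    names["T_PLANTED"] = "planted above-high-parent term"
    ann = AnnotationMap(terms=terms, term_names=names)

    paths = {
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "truth": outdir / "truth.tsv",
        "annotation": outdir / "annotation.gmt",
    }
    write_count_matrix(counts, paths["counts"])
    write_design(design, paths["design"])
    write_gene_lengths(lengths, paths["lengths"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_annotation_gmt(ann, paths["annotation"])
    return paths


def fixture_digest(paths: Mapping[str, Path]) -> dict[str, str]:
    """SHA-256 of each fixture file, for determinism checks."""
    return {
        k: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        for k, p in sorted(paths.items())
    }
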