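"""File readers, variant-set extraction, environment construction and the
voxelwise driver.

Genotypes arrive either as a delimited subjects x SNPs matrix or as a VCF
(biallelic diploid sites; parsed with cyvcf2).  Coding is the minor-allele
count 0/1/2 relative to the analysis sample: whichever allele has sample
frequency below one half counts, ties resolved to ALT.  Variant sets are
genomic intervals padded by a +-20 kb flank (inclusive, 1-based) or
explicit SNP-id lists.  When several risk variables stand in for a single
exposure, the first principal component of the standardized variables is
used as the environment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import DesignBundle, LinkSpec, prune_columns
from .multiple_testing import QValueResult, storey_qvalues
from .pvalue_dist import ChiSquareMixture, P_FLOOR, mixture_sf
from .score_tests import EIG_REL_TOL, SIGMA_REL_TOL, mixge_test

logger = logging.getLogger("mixge")

__all__ = [
    "VariantSetDefinition",
    "VoxelwisePhenotype",
    "read_genotypes",
    "read_vcf_genotypes",
    "read_delimited_genotypes",
    "write_delimited_genotypes",
    "extract_variant_set",
    "build_environment_pc1",
    "run_voxelwise",
    "read_table",
    "check_aligned",
]

DEFAULT_FLANK = 20_000


@dataclass
class VariantSetDefinition:
    """A named variant set: explicit SNP ids, or an interval with a flank.

    Interval coordinates are 1-based and inclusive; the flank extends the
    interval to ``[start - flank, end + flank]``, both endpoints included.
    """

    set_name: str
    snp_ids: list[str] | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.snp_ids is None and self.chrom is None:
            raise ValueError("give either snp_ids or a genomic interval")
        if self.chrom is not None:
            if self.start is None or self.end is None or self.start > self.end:
                raise ValueError("interval needs start <= end")
            if self.flank < 0:
                raise ValueError("flank must be nonnegative")


@dataclass
class VoxelwisePhenotype:
    """Subjects x voxels phenotype matrix, optionally tied to a 3-D grid."""

    matrix: np.ndarray
    voxel_ids: list[str] | None = None
    grid_shape: tuple[int, ...] | None = None
    grid_index: np.ndarray | None = None    # flat indices into the grid
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.voxel_ids is None:
            self.voxel_ids = [f"v{j}" for j in range(self.matrix.shape[1])]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]


def read_table(path, **kwargs) -> pd.DataFrame:
    """CSV/TSV/semicolon sniffing reader for small delimited tables.

    Falls back to comma when the delimiter cannot be inferred (e.g. a
    single-column file).
    """
    import csv

    with open(path, "r") as fh:
        sample = fh.read(8192)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        sep = ","
    return pd.read_csv(path, sep=sep, **kwargs)


def check_aligned(n: int, **named_lengths: int) -> None:
    """Assert row-count consistency across input files (truncation guard)."""
    bad = {k: v for k, v in named_lengths.items() if v != n}
    if bad:
        raise ValueError(f"row-count mismatch: expected {n} subjects, got {bad}")


def _minor_allele_recode(alt_counts: np.ndarray) -> tuple[np.ndarray, bool]:
    """Flip ALT-allele counts to minor-allele counts if ALT is the major allele.

    The minor allele is the one with observed sample frequency < 0.5; an
    exact tie keeps ALT as minor.  Missing entries (NaN) are ignored in the
    frequency and preserved in the output.
    """
    obs = alt_counts[~np.isnan(alt_counts)]
    if obs.size == 0:
        return alt_counts, False
    freq = obs.sum() / (2.0 * obs.size)
    if freq > 0.5:
        return 2.0 - alt_counts, True
    return alt_counts, False


def read_vcf_genotypes(path: str) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a VCF into a minor-allele-count matrix plus SNP metadata.

    Non-biallelic sites are skipped (count logged); missing diploid calls
    become NaN and are mean-imputed downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    meta: list[dict] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gt = np.asarray(var.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gt], dtype=float)
        alleles[alleles < 0] = np.nan
        counts = alleles.sum(axis=1)
        counts, flipped = _minor_allele_recode(counts)
        cols.append(counts)
        meta.append({
            "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
            "chrom": str(var.CHROM),
            "pos": int(var.POS),
            "ref": var.REF,
            "alt": var.ALT[0],
            "flipped": flipped,
        })
    if skipped:
        logger.info("skipped %d non-biallelic site(s)", skipped)
    if not cols:
        raise ValueError(f"no biallelic sites found in {path}")
    G = np.column_stack(cols)
    md = pd.DataFrame(meta)
    md.attrs["samples"] = samples
    return G, md


def read_delimited_genotypes(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a delimited subjects x SNPs matrix (header row of SNP ids)."""
    df = read_table(path)
    G = df.to_numpy(dtype=float)
    md = pd.DataFrame({"snp_id": list(df.columns),
                       "chrom": pd.NA, "pos": pd.NA,
                       "ref": pd.NA, "alt": pd.NA, "flipped": False})
    return G, md


def write_delimited_genotypes(path, G: np.ndarray, snp_ids: list[str] | None = None) -> None:
    ids = snp_ids or [f"snp{j}" for j in range(np.atleast_2d(G).shape[1])]
    pd.DataFrame(np.atleast_2d(G), columns=ids).to_csv(path, sep="\t", index=False)


def read_genotypes(path, format: str = "delimited") -> tuple[np.ndarray, pd.DataFrame]:
    """Dispatch genotype reading by format (``vcf`` or ``delimited``)."""
    if format == "vcf":
        return read_vcf_genotypes(str(path))
    if format == "delimited":
        return read_delimited_genotypes(path)
    raise ValueError(f"unknown genotype format {format!r}")


def extract_variant_set(snp_metadata: pd.DataFrame,
                        definition: VariantSetDefinition) -> np.ndarray:
    """Column indices of the SNPs belonging to one variant set.

    Interval sets select SNPs with ``start - flank <= pos <= end + flank``
    on the matching chromosome (inclusive, 1-based); id sets select by
    exact ``snp_id`` match.  An empty result warns rather than raises.
    """
    if definition.snp_ids is not None:
        wanted = set(definition.snp_ids)
        idx = np.flatnonzero(snp_metadata["snp_id"].isin(wanted).to_numpy())
    else:
        lo = definition.start - definition.flank
        hi = definition.end + definition.flank
        chrom = snp_metadata["chrom"].astype(str).to_numpy()
        pos = pd.to_numeric(snp_metadata["pos"], errors="coerce").to_numpy(dtype=float)
        sel = (chrom == str(definition.chrom)) & (pos >= lo) & (pos <= hi)
        idx = np.flatnonzero(sel)
    if idx.size == 0:
        logger.warning("variant set %s matched no SNPs", definition.set_name)
    return idx


def build_environment_pc1(env_table: pd.DataFrame | np.ndarray,
                          ) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of several standardized risk variables.

    Columns are standardized to mean 0, variance 1 (sample sd); the PC1
    score vector, its loadings and the fraction of total variance explained
    are returned.  The sign is fixed so the largest-magnitude loading is
    positive.
    """
    if isinstance(env_table, pd.DataFrame):
        names = list(env_table.columns)
        Xe = env_table.to_numpy(dtype=float)
    else:
        Xe = np.atleast_2d(np.asarray(env_table, dtype=float))
        names = [f"var{j}" for j in range(Xe.shape[1])]
    if Xe.shape[1] < 2:
        raise ValueError("need at least two risk variables for a principal component")
    sd = Xe.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(f"constant risk variable(s): {[names[j] for j in const]}")
    Z = (Xe - Xe.mean(axis=0)) / sd
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    scores = Z @ loadings
    var_fraction = float(s[0] ** 2 / (s ** 2).sum())
    return scores, loadings, var_fraction


def _voxelwise_identity(template: DesignBundle, Y: np.ndarray,
                        main_effects: str = "per-snp") -> pd.DataFrame:
    """Vectorised identity-link MixGE across voxels sharing one design.

    Everything voxel-independent — design pruning, projection bases, the
    unit-variance eigenvalue set of the projected kernel and the score
    covariance — is computed once; per-voxel work reduces to two projected
    residual vectors and a handful of inner products.  With a common
    residual variance the eigenvalues and Sigma scale linearly in the
    per-voxel variance estimate, so p-values follow from the shared shapes.
    """
    n, n_vox = Y.shape
    M = template.design_tau(main_effects)
    V = template.design_full(main_effects)
    Mk = M[:, prune_columns(M)]
    Vk = V[:, prune_columns(V)]
    Qm, _ = np.linalg.qr(Mk)
    Qv, _ = np.linalg.qr(Vk)
    A = template.E[:, None] * template.G
    B = template.E[:, None] * template.burden()

    # unit-variance eigenvalues of the projected kernel (tau score)
    PA = A - Qm @ (Qm.T @ A)
    core = A.T @ PA
    core = 0.5 * (core + core.T)
    eigs = np.linalg.eigvalsh(core)[::-1]
    eigs = eigs[eigs > EIG_REL_TOL * max(eigs[0], 0.0)] if eigs.size and eigs[0] > 0 else np.empty(0)
    base_mix = ChiSquareMixture(eigs) if eigs.size else None

    # unit-variance score covariance (pi score)
    PB = B - Qv @ (Qv.T @ B)
    Sigma0 = B.T @ PB
    Sigma0 = 0.5 * (Sigma0 + Sigma0.T)
    evals, evecs = np.linalg.eigh(Sigma0)
    keep = evals > SIGMA_REL_TOL * max(evals.max(), 0.0) if evals.size else np.empty(0, bool)
    df = int(keep.sum())
    Sigma0_inv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T if df else None

    # residuals under both nulls, all voxels at once
    R_tau = Y - Qm @ (Qm.T @ Y)
    R_full = Y - Qv @ (Qv.T @ Y)
    # common-variance estimates with the same n/(n-k) inflation as the fits
    s2_tau = np.einsum("ij,ij->j", R_tau, R_tau) / (n - Mk.shape[1])
    s2_full = np.einsum("ij,ij->j", R_full, R_full) / (n - Vk.shape[1])
    # constant phenotype columns are untestable: flag, force p = 1
    zero_var = (np.ptp(Y, axis=0) == 0) | (s2_tau <= 0)
    s2_tau = np.where(zero_var, 0.0, s2_tau)
    s2_full = np.where(zero_var, 0.0, s2_full)

    AtR = A.T @ R_tau
    S = np.einsum("ij,ij->j", AtR, AtR)
    U = B.T @ R_full

    p_tau = np.ones(n_vox)
    ok_tau = (s2_tau > 0) & (base_mix is not None)
    if base_mix is not None and ok_tau.any():
        p_tau[ok_tau] = np.clip(mixture_sf(S[ok_tau] / s2_tau[ok_tau], base_mix),
                                P_FLOOR, 1.0)
    p_pi = np.ones(n_vox)
    if Sigma0_inv is not None:
        quad = np.einsum("ij,ij->j", U, Sigma0_inv @ U)
        ok_pi = s2_full > 0
        p_pi[ok_pi] = np.clip(stats.chi2.sf(quad[ok_pi] / s2_full[ok_pi], df=df),
                              P_FLOOR, 1.0)
    p_pi[zero_var] = 1.0
    p_tau[zero_var] = 1.0

    stat = -2.0 * (np.log(np.maximum(p_pi, P_FLOOR)) + np.log(np.maximum(p_tau, P_FLOOR)))
    p_fisher = np.clip(stats.chi2.sf(stat, df=4), P_FLOOR, 1.0)
    pmin = np.minimum(p_pi, p_tau)
    p_tippett = np.clip(1.0 - (1.0 - pmin) ** 2, P_FLOOR, 1.0)
    return pd.DataFrame({
        "p_pi": p_pi, "p_tau": p_tau, "p_fisher": p_fisher,
        "p_tippett": p_tippett, "zero_variance": zero_var,
    })


def run_voxelwise(template: DesignBundle, phenotypes: VoxelwisePhenotype,
                  link: LinkSpec, q_cutoff: float = 0.05,
                  combine: str = "fisher",
                  exclude_degenerate_from_fdr: bool = True,
                  main_effects: str = "per-snp",
                  ) -> tuple[pd.DataFrame, QValueResult]:
    """Per-voxel MixGE tests with Storey FDR on the combined p-values.

    The covariates, environment, genotypes and weights of ``template`` are
    shared across voxels; only the phenotype changes.  The identity link
    uses a fully vectorised path; the logit link loops voxels.  Returns the
    per-voxel result table (with a ``q_value`` and ``significant`` column)
    and the q-value object.
    """
    Y = phenotypes.matrix
    if Y.shape[0] != template.n_subjects:
        raise ValueError(
            f"phenotype matrix has {Y.shape[0]} subjects, design has {template.n_subjects}"
        )
    if combine not in ("fisher", "tippett"):
        raise ValueError("combine must be 'fisher' or 'tippett'")
    if link.is_logit:
        rows = []
        for j in range(Y.shape[1]):
            bundle = DesignBundle(Y=Y[:, j], X=template.X, E=template.E,
                                  G=template.G, W=template.W)
            res = mixge_test(bundle, link, compute_random=False,
                             main_effects=main_effects)
            rows.append({"p_pi": res.p_pi, "p_tau": res.p_tau,
                         "p_fisher": res.p_fisher, "p_tippett": res.p_tippett,
                         "zero_variance": False})
        table = pd.DataFrame(rows)
    else:
        table = _voxelwise_identity(template, Y, main_effects)
    table.insert(0, "voxel", phenotypes.voxel_ids)

    p_comb = table[f"p_{combine}"].to_numpy()
    if exclude_degenerate_from_fdr and table["zero_variance"].any():
        usable = ~table["zero_variance"].to_numpy()
        qres_sub = storey_qvalues(p_comb[usable])
        q = np.ones(p_comb.size)
        q[usable] = qres_sub.qvalues
        qres = QValueResult(q, qres_sub.pi0, qres_sub.lambda_param, p_comb)
    else:
        qres = storey_qvalues(p_comb)
    table["q_value"] = qres.qvalues
    table["significant"] = qres.qvalues <= q_cutoff
    return table, qres
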