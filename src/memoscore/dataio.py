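"""Readers/writers, allele bookkeeping, and ancestry principal components.

In-memory containers
--------------------
:class:`GenotypePanel` holds a samples x variants dosage matrix (expected
effect-allele counts in [0, 2], NaN for missing) together with per-variant
metadata.  Tabular objects — summary statistics, weight tables, cohort
phenotype/covariate tables — are plain :class:`pandas.DataFrame` objects with
documented column schemas, validated by the helpers below.

Supported genotype dialects: an internal TSV dosage dialect (header:
``sample_id`` then variant ids, one row per sample), PLINK1 bed/bim/fam
(hard calls), and VCF (dosage from the ``DS`` FORMAT field when present,
else summed hard calls).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "p", "n"]
WEIGHT_COLUMNS = ["feature_id", "effect_allele", "weight", "source_label"]

#: strand-ambiguous (palindromic) allele pairs
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant metadata.

    Parameters
    ----------
    sample_ids : array of str, length n_samples
    variants : DataFrame with columns ``variant_id, chrom, pos,
        effect_allele, other_allele`` (``pos`` is 1-based, BIM/VCF convention)
    dosages : float array (n_samples, n_variants), values in [0, 2] or NaN
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        vid = self.variants["variant_id"]
        if vid.duplicated().any():
            dups = vid[vid.duplicated()].tolist()
            raise DataError(f"duplicated variant id(s): {dups[:5]}")
        if pd.Index(self.sample_ids).duplicated().any():
            raise DataError("duplicated sample ids")
        same = self.variants["effect_allele"] == self.variants["other_allele"]
        if same.any():
            raise DataError(
                f"effect allele equals other allele for {vid[same].tolist()[:5]}"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < -1e-9) | (self.dosages > 2 + 1e-9)
        if np.any(bad):
            raise DataError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def subset_samples(self, mask_or_idx) -> "GenotypePanel":
        idx = np.asarray(mask_or_idx)
        return GenotypePanel(self.sample_ids[idx], self.variants.copy(), self.dosages[idx])

    def subset_variants(self, ids) -> "GenotypePanel":
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        idx = np.array([pos[v] for v in ids], dtype=int)
        return GenotypePanel(
            self.sample_ids, self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )


# ---------------------------------------------------------------------------
# schema validation helpers


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"summary-stats table missing columns {missing}")
    ok = df["beta"].notna()
    if (df.loc[ok, "se"] <= 0).any():
        raise DataError("summary-stats table has se <= 0")
    p = df.loc[ok, "p"]
    if ((p <= 0) | (p > 1)).any():
        raise DataError("summary-stats table has p outside (0, 1]")
    if df["variant_id"].duplicated().any():
        raise DataError("summary-stats table has duplicated variant ids")
    return df


def validate_weights(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"weight table missing columns {missing}")
    if df["feature_id"].duplicated().any():
        raise DataError("weight table has duplicated feature ids")
    if not np.isfinite(df["weight"].to_numpy(dtype=float)).all():
        raise DataError("weight table has non-finite weights")
    return df


def empty_weight_table(source_label: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"feature_id": pd.Series(dtype=object),
         "effect_allele": pd.Series(dtype=object),
         "weight": pd.Series(dtype=float),
         "source_label": pd.Series(dtype=object)}
    ).assign(source_label=source_label)[WEIGHT_COLUMNS]


# ---------------------------------------------------------------------------
# genotype readers / writers


def read_genotypes(path, dialect: str = "tsv") -> GenotypePanel:
    """Read a genotype panel from ``tsv``, ``plink`` or ``vcf`` dialects.

    For ``plink`` pass the file-set prefix (``prefix.bed/.bim/.fam``).
    """
    if dialect == "tsv":
        return _read_tsv_dosages(Path(path))
    if dialect == "plink":
        return _read_plink(Path(path))
    if dialect == "vcf":
        return _read_vcf(Path(path))
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(panel: GenotypePanel, path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        _write_tsv_dosages(panel, Path(path))
    elif dialect == "plink":
        _write_plink(panel, Path(path))
    elif dialect == "vcf":
        _write_vcf(panel, Path(path))
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_tsv_dosages(path: Path) -> GenotypePanel:
    meta_path = path.with_suffix(path.suffix + ".variants")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise DataError(f"{path}: first column must be 'sample_id'")
    variant_ids = list(df.columns[1:])
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    if meta_path.exists():
        variants = pd.read_csv(meta_path, sep="\t", dtype={"variant_id": str})
    else:  # minimal metadata for a bare dosage file
        variants = pd.DataFrame(
            {"variant_id": variant_ids, "chrom": "1",
             "pos": np.arange(1, len(variant_ids) + 1),
             "effect_allele": "A", "other_allele": "G"}
        )
    if list(variants["variant_id"]) != variant_ids:
        raise DataError(f"{meta_path}: variant ids disagree with dosage header")
    return GenotypePanel(df["sample_id"].to_numpy(object), variants, dosages)


def _write_tsv_dosages(panel: GenotypePanel, path: Path) -> None:
    out = pd.DataFrame(panel.dosages, columns=panel.variant_ids)
    out.insert(0, "sample_id", panel.sample_ids)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    panel.variants.to_csv(
        path.with_suffix(path.suffix + ".variants"), sep="\t", index=False
    )


# --- PLINK1 bed/bim/fam (hard calls, SNP-major) ---

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit codes, effect allele = BIM A1: 00 hom A1 (dosage 2), 10 het (1),
# 11 hom A2 (0), 01 missing
_BED_DECODE = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}


def _read_plink(prefix: Path) -> GenotypePanel:
    fam = pd.read_csv(
        Path(str(prefix) + ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"), sep=r"\s+", header=None,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(str(prefix) + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise DataError(f"{prefix}.bed: not a SNP-major PLINK1 bed file")
    stride = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != stride * m:
        raise DataError(f"{prefix}.bed: size inconsistent with fam/bim")
    codes = body.reshape(m, stride)
    # unpack 2-bit fields, sample-fastest within byte
    lut = np.empty(4, dtype=float)
    for code, dose in _BED_DECODE.items():
        lut[code] = dose
    dosages = np.empty((n, m), dtype=float)
    shifts = np.arange(4) * 2
    expanded = (codes[:, :, None] >> shifts[None, None, :]) & 0b11  # (m, stride, 4)
    expanded = expanded.reshape(m, stride * 4)[:, :n]
    dosages[:] = lut[expanded].T
    variants = pd.DataFrame(
        {"variant_id": bim["variant_id"], "chrom": bim["chrom"],
         "pos": bim["pos"].astype(int),
         "effect_allele": bim["a1"], "other_allele": bim["a2"]}
    )
    return GenotypePanel(fam["iid"].to_numpy(object), variants, dosages)


def _write_plink(panel: GenotypePanel, prefix: Path) -> None:
    n, m = panel.n_samples, panel.n_variants
    fam = pd.DataFrame(
        {"fid": panel.sample_ids, "iid": panel.sample_ids, "pat": 0, "mat": 0,
         "sex": 0, "pheno": -9}
    )
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {"chrom": panel.variants["chrom"], "variant_id": panel.variants["variant_id"],
         "cm": 0, "pos": panel.variants["pos"],
         "a1": panel.variants["effect_allele"], "a2": panel.variants["other_allele"]}
    )
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)
    # hard-call rounding of dosages to nearest integer; NaN -> missing code
    rounded = np.round(panel.dosages)
    code = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    gt = rounded.T
    code[gt == 2] = 0b00
    code[gt == 1] = 0b10
    code[gt == 0] = 0b11
    stride = (n + 3) // 4
    padded = np.full((m, stride * 4), 0b01, dtype=np.uint8)
    padded[:, :n] = code
    packed = np.zeros((m, stride), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# --- VCF ---


def _read_vcf(path: Path) -> GenotypePanel:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc
    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    rows, ids, chroms, poss, ref, alt = [], [], [], [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise DataError(f"{path}: record {i + 1} is not biallelic")
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(rec.genotype.array())[:, :2]
            dose = np.where((gts < 0).any(axis=1), np.nan,
                            (gts > 0).sum(axis=1).astype(float))
        rows.append(dose)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
    variants = pd.DataFrame(
        {"variant_id": ids, "chrom": chroms, "pos": poss,
         "effect_allele": alt, "other_allele": ref}  # dosage counts ALT
    )
    return GenotypePanel(samples, variants, np.array(rows).T)


def _write_vcf(panel: GenotypePanel, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.sample_ids)) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(panel.n_variants):
            v = panel.variants.iloc[j]
            cells = []
            for d in panel.dosages[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_map.get(int(round(d)), './.')}:{d:.4g}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.other_allele}\t"
                f"{v.effect_allele}\t.\t.\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# tabular io


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ancestry PCs


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (all-NaN columns -> 0)."""
    out = np.array(dosages, dtype=float)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(out)
    out[nan_mask] = np.broadcast_to(col_mean, out.shape)[nan_mask]
    return out


def compute_ancestry_pcs(panel: GenotypePanel, k: int = 3) -> np.ndarray:
    """Top-k principal components of the column-standardized dosage matrix.

    Missing dosages are mean-imputed per variant; zero-variance variants are
    dropped.  Each returned column has zero mean and unit variance (ddof=1),
    with the sign fixed so that the largest-magnitude variant loading is
    positive.
    """
    if k >= min(panel.n_samples, panel.n_variants):
        raise ValueError("k must be below min(n_samples, n_variants)")
    X = mean_impute(panel.dosages)
    sd = X.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("compute_ancestry_pcs: dropped %d zero-variance variants", n_dropped)
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if min(X.shape) > 500:
        # truncated SVD with a fixed start vector keeps large panels fast
        # and deterministic
        from scipy.sparse.linalg import svds
        v0 = np.ones(min(X.shape))
        U, s, Vt = svds(X, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    else:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :k]
    # sign convention: largest-|loading| positive
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            pcs[:, j] = -pcs[:, j]
    pcs = pcs - pcs.mean(axis=0)
    pcs = pcs / pcs.std(axis=0, ddof=1)
    return pcs


# ---------------------------------------------------------------------------
# allele harmonization


def harmonize_alleles(weights: pd.DataFrame, panel: GenotypePanel):
    """Align a variant weight table to a panel's allele encoding.

    Variants are matched by id.  When the weight's effect allele equals the
    panel's *other* allele (directly or as the strand complement), the panel
    dosage is to be read as ``2 - g`` for that variant: the returned table
    keeps the weight unchanged and marks the row in a boolean ``flipped``
    column, which :func:`memoscore.scoring.score_genetic` honours.
    Strand-ambiguous (A/T, C/G) panel variants are dropped, as are variants
    absent from the panel or with irreconcilable alleles.

    Returns ``(aligned_weights, report)`` with report counts
    ``{matched, flipped, ambiguous_dropped, missing, irreconcilable}``.
    """
    validate_weights(weights)
    pv = panel.variants.set_index("variant_id")
    report = {"matched": 0, "flipped": 0, "ambiguous_dropped": 0,
              "missing": 0, "irreconcilable": 0}
    rows = []
    for row in weights.itertuples(index=False):
        if row.feature_id not in pv.index:
            report["missing"] += 1
            continue
        pair = pv.loc[row.feature_id]
        p_ea = str(pair["effect_allele"]).upper()
        p_oa = str(pair["other_allele"]).upper()
        ea = str(row.effect_allele).upper()
        # ambiguity is decided from the panel's allele pair (the weight table
        # carries only the effect allele)
        if (p_ea, p_oa) in _AMBIGUOUS_PAIRS:
            report["ambiguous_dropped"] += 1
            continue
        if ea == p_ea or _COMPLEMENT.get(ea) == p_ea:
            rows.append((row.feature_id, str(row.effect_allele),
                         float(row.weight), row.source_label, False))
            report["matched"] += 1
        elif ea == p_oa or _COMPLEMENT.get(ea) == p_oa:
            rows.append((row.feature_id, str(row.effect_allele),
                         float(row.weight), row.source_label, True))
            report["matched"] += 1
            report["flipped"] += 1
        else:
            report["irreconcilable"] += 1
            logger.info("harmonize_alleles: dropping %s (alleles irreconcilable)",
                        row.feature_id)
    if not rows:
        raise DataError("harmonize_alleles: zero matched variants")
    aligned = pd.DataFrame(rows, columns=WEIGHT_COLUMNS + ["flipped"])
    return aligned, report
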