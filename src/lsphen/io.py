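"""File formats: 8-bit PNG for RGB, 32-bit float single-band TIFF for DSMs,
0/255 PNG masks, CSV tables, plain VCF for genotypes, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .preprocess import TRAITS, PlotImagePair
from .synthetic_data import GenotypeMatrix

# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_rgb_png(rgb: np.ndarray, path: Path | str) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)


def read_rgb_png(path: Path | str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_mask_png(mask: np.ndarray, path: Path | str) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255)), mode="L").save(path)


def read_mask_png(path: Path | str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_dsm_tiff(dsm: np.ndarray, path: Path | str) -> None:
    tifffile.imwrite(path, np.asarray(dsm, dtype=np.float32))


def read_dsm_tiff(path: Path | str) -> np.ndarray:
    return tifffile.imread(path).astype(np.float32)


def write_pair(pair: PlotImagePair, directory: Path | str) -> dict:
    """Write one plot's rgb/dsm/mask files; returns relative file names."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = {
        "rgb": f"{pair.plot_id}_rgb.png",
        "dsm": f"{pair.plot_id}_dsm.tif",
        "mask": f"{pair.plot_id}_mask.png",
    }
    write_rgb_png(pair.rgb, directory / names["rgb"])
    write_dsm_tiff(pair.dsm, directory / names["dsm"])
    write_mask_png(pair.mask, directory / names["mask"])
    return names


def read_pair(directory: Path | str, plot_id: str) -> PlotImagePair:
    directory = Path(directory)
    return PlotImagePair(
        rgb=read_rgb_png(directory / f"{plot_id}_rgb.png"),
        dsm=read_dsm_tiff(directory / f"{plot_id}_dsm.tif"),
        mask=read_mask_png(directory / f"{plot_id}_mask.png"),
        plot_id=plot_id,
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_traits_csv(plots: pd.DataFrame, plot_traits: pd.DataFrame, path: Path | str) -> None:
    """One row per plot: plot_id, accession, treatment, replicate, DW..PH."""
    merged = plots.merge(
        plot_traits.reset_index(names="plot_id"), on="plot_id", validate="1:1"
    )
    merged.to_csv(path, index=False)


def read_traits_csv(path: Path | str) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path)
    plots = df[["plot_id", "accession", "treatment", "replicate"]]
    traits = df.set_index("plot_id")[list(TRAITS)]
    return plots, traits


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_GT_OF_SCORE = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}


def write_genotypes_vcf(geno: GenotypeMatrix, path: Path | str) -> None:
    """Plain uncompressed VCF with biallelic records and GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accession_ids)
            + "\n"
        )
        for j, snp in enumerate(geno.snp_ids):
            gts = [
                "./." if np.isnan(s) else _GT_OF_SCORE[float(s)]
                for s in geno.scores[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_genotypes_vcf(path: Path | str) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: only needed when reading VCFs

    vcf = VCF(str(path))
    accession_ids = list(vcf.samples)
    snp_ids, columns = [], []
    for variant in vcf:
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        col = np.full(len(accession_ids), np.nan)
        for i, gt in enumerate(variant.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 >= 0 and a1 >= 0:
                col[i] = a0 + a1 - 1.0
        columns.append(col)
    vcf.close()
    return GenotypeMatrix(
        scores=np.column_stack(columns) if columns else np.empty((len(accession_ids), 0)),
        snp_ids=snp_ids,
        accession_ids=accession_ids,
    )


def write_genotypes_csv(geno: GenotypeMatrix, path: Path | str) -> None:
    pd.DataFrame(
        geno.scores, index=geno.accession_ids, columns=geno.snp_ids
    ).to_csv(path, index_label="accession")


def read_genotypes_csv(path: Path | str) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="accession")
    return GenotypeMatrix(
        scores=df.to_numpy(dtype=float),
        snp_ids=list(df.columns),
        accession_ids=[str(a) for a in df.index],
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def write_json(obj: dict, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def read_json(path: Path | str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
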