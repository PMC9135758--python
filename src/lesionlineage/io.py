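"""Readers/writers for the pipeline's standard formats.

VCF 4.2 (het-site allele depths, via cyvcf2 on read), fixed-step WIG
(log-ratio tracks), IGV-dialect SEG (1-based inclusive coordinates on disk;
everything in memory stays 0-based half-open), TSV tables and YAML manifests.
All writers are deterministic byte-for-byte for identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .clonal_inference import ClonalModel, TypedSegment
from .genome import BinDepth, GenomeLayout, HetSite
from .lineage import LineageCall, SharedFeatureReport
from .states import GenotypeState

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- run log


@dataclass
class RunLog:
    """Stage records, parameter echo and warnings for one pipeline run."""

    version: str = "0.1.0"
    records: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, **params) -> None:
        self.records.append(
            {
                "stage": stage,
                "time": datetime.now(timezone.utc).isoformat(),
                "params": params,
            }
        )

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)

    def write(self, path) -> None:
        payload = {
            "software": {"name": "lesionlineage", "version": self.version},
            "stages": self.records,
            "warnings": self.warnings,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------- WIG


def write_wig(path, bins: list[BinDepth], layout: GenomeLayout) -> None:
    lr = layout.log_ratio_vector(bins)
    lines = []
    for name in layout.chrom_names:
        sl = layout.chrom_slices[name]
        lines.append(
            f"fixedStep chrom={name} start=1 step={layout.bin_size} span={layout.bin_size}"
        )
        for v in lr[sl]:
            lines.append("NA" if not np.isfinite(v) else f"{v:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_wig(path, layout: GenomeLayout, run_log: RunLog | None = None) -> list[BinDepth]:
    """Fixed-step WIG -> one BinDepth per layout bin (NaN where missing)."""
    lr = np.full(layout.n_bins, np.nan)
    chrom = None
    cursor = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("track"):
            continue
        if line.startswith("fixedStep"):
            fields = dict(kv.split("=") for kv in line.split()[1:])
            chrom = fields["chrom"]
            if chrom not in layout.chrom_slices:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom}")
            step = int(fields.get("step", layout.bin_size))
            if step != layout.bin_size:
                raise FormatError(
                    f"{path}:{lineno}: step {step} != layout bin size {layout.bin_size}"
                )
            start = int(fields.get("start", 1)) - 1
            cursor = layout.chrom_slices[chrom].start + start // layout.bin_size
        else:
            if chrom is None:
                raise FormatError(f"{path}:{lineno}: value before fixedStep header")
            if cursor >= layout.chrom_slices[chrom].stop:
                raise FormatError(f"{path}:{lineno}: more values than bins on {chrom}")
            if line != "NA":
                lr[cursor] = float(line)
            cursor += 1
    n_missing = int(np.sum(~np.isfinite(lr)))
    if n_missing and run_log is not None:
        run_log.warn(f"{path}: {n_missing} bins without a log-ratio value (NA)")
    names = layout.chrom_names
    return [
        BinDepth(names[ci], int(s), int(e), float(v))
        for ci, s, e, v in zip(
            layout.bin_chrom_idx, layout.bin_start, layout.bin_end, lr
        )
    ]


# ---------------------------------------------------------------- VCF


def write_het_vcf(path, sites: list[HetSite], layout: GenomeLayout, sample: str = "TUMOR") -> None:
    """Het sites as a minimal single-sample VCF 4.2 with GT:AD:DP.

    REF/ALT bases are synthetic placeholders (A/C): no sequence is simulated.
    """
    lines = ["##fileformat=VCFv4.2"]
    for name, length in layout.chromosomes:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for s in sites:
        ad = f"{s.ref_count},{s.depth - s.ref_count}"
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\tA\tC\t.\tPASS\t.\tGT:AD:DP\t0/1:{ad}:{s.depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_het_vcf(path, min_depth: int = 10, run_log: RunLog | None = None) -> list[HetSite]:
    """Biallelic SNVs with AD-style allele depths, depth >= ``min_depth``.

    Multiallelic, non-SNV and shallow records are excluded (counted in the run
    log); a record without allele-depth information is a format error.
    """
    sites: list[HetSite] = []
    n_multi = n_nonsnp = n_shallow = 0
    for v in VCF(str(path)):
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if not v.is_snp:
            n_nonsnp += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: record {v.CHROM}:{v.POS} has no AD (allele depth) field"
            )
        ref, alt = int(ad[0][0]), int(ad[0][1])
        depth = ref + alt
        if depth < min_depth:
            n_shallow += 1
            continue
        sites.append(HetSite(v.CHROM, v.POS, ref, depth))
    if run_log is not None:
        for count, why in ((n_multi, "multiallelic"), (n_nonsnp, "non-SNV"),
                           (n_shallow, f"depth < {min_depth}")):
            if count:
                run_log.warn(f"{path}: excluded {count} {why} records")
    order = {c: i for i, c in enumerate(dict.fromkeys(s.chrom for s in sites))}
    sites.sort(key=lambda s: (order[s.chrom], s.pos))
    return sites


# ---------------------------------------------------------------- SEG


TYPED_SEG_COLUMNS = [
    "sample", "chrom", "start", "end", "n_loci", "mean_log_ratio",
    "mean_allelic_ratio", "c", "a", "loh_label", "cnv_label", "cluster",
    "prevalence",
]


def write_typed_seg(
    path, segments: list[TypedSegment], sample: str = "lesion",
    prevalences: dict[int, float] | None = None,
) -> None:
    """Typed segments as a SEG-style TSV (1-based inclusive on disk)."""
    rows = []
    for s in segments:
        rows.append({
            "sample": sample,
            "chrom": s.chrom,
            "start": s.start + 1,
            "end": s.end,
            "n_loci": s.n_loci,
            "mean_log_ratio": round(s.mean_log_ratio, 6),
            "mean_allelic_ratio": round(s.mean_allelic_ratio, 6)
            if np.isfinite(s.mean_allelic_ratio) else "NA",
            "c": s.genotype.c,
            "a": s.genotype.a,
            "loh_label": s.genotype.loh_label,
            "cnv_label": s.genotype.cnv_label,
            "cluster": s.cluster,
            "prevalence": round(prevalences.get(s.cluster, float("nan")), 6)
            if prevalences else "NA",
        })
    pd.DataFrame(rows, columns=TYPED_SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_typed_seg(path) -> list[TypedSegment]:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    segs = []
    for row in df.itertuples():
        segs.append(
            TypedSegment(
                chrom=str(row.chrom),
                start=int(row.start) - 1,
                end=int(row.end),
                genotype=GenotypeState(int(row.c), int(row.a)),
                cluster=int(row.cluster),
                mean_log_ratio=float(row.mean_log_ratio),
                mean_allelic_ratio=float(row.mean_allelic_ratio)
                if pd.notna(row.mean_allelic_ratio) else float("nan"),
                n_loci=int(row.n_loci),
            )
        )
    return segs


def write_cnv_seg(path, segments, sample: str = "sample") -> None:
    """Depth-HMM segments: standard SEG plus a sidecar .calls.tsv with the call."""
    rows = [
        {
            "ID": sample, "chrom": s.chrom, "loc.start": s.start + 1,
            "loc.end": s.end, "num.mark": s.n_bins,
            "seg.median": round(s.median_log_ratio, 6),
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    calls = pd.DataFrame(
        {"chrom": [s.chrom for s in segments],
         "start": [s.start + 1 for s in segments],
         "end": [s.end for s in segments],
         "call": [s.call for s in segments]}
    )
    calls.to_csv(str(path) + ".calls.tsv", sep="\t", index=False)


# ---------------------------------------------------------------- YAML summaries


def write_model_yaml(path, model: ClonalModel) -> None:
    payload = {
        "normal_fraction": round(model.normal_fraction, 6),
        "clusters": [
            {"id": cid, "prevalence": round(s, 6)} for cid, s in model.clusters
        ],
        "sigma": round(model.sigma, 6),
        "rho": model.rho,
        "log_likelihood": round(model.log_likelihood, 4),
        "n_clusters": model.n_clusters,
        "n_iterations": model.n_iterations,
        "converged": bool(model.converged),
        "bic": round(model.bic, 4) if model.bic is not None else None,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def write_call_yaml(path, call: LineageCall) -> None:
    payload = {
        "verdict": call.verdict,
        "pearson_r": round(call.r, 6) if call.r is not None else None,
        "top_shared_fraction": round(call.top_shared_fraction, 6),
        "r_threshold": call.r_threshold,
        "share_threshold": call.share_threshold,
        "evidence": call.notes,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def write_share_matrix(path, report: SharedFeatureReport) -> None:
    rows = [
        {
            "cluster_a": p.cluster_a, "cluster_b": p.cluster_b,
            "n_shared": p.n_shared, "n_unique_a": p.n_unique_a,
            "n_unique_b": p.n_unique_b,
            "shared_fraction": round(p.shared_fraction, 6),
        }
        for p in report.pairs
    ]
    pd.DataFrame(
        rows,
        columns=["cluster_a", "cluster_b", "n_shared", "n_unique_a",
                 "n_unique_b", "shared_fraction"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- manifest


@dataclass
class Manifest:
    patient: str
    lesions: list[dict]  # {label, vcf, wig}
    normal_label: str
    params: dict

    def lesion_labels(self) -> list[str]:
        return [l["label"] for l in self.lesions]


def write_manifest(path, manifest: Manifest) -> None:
    payload = {
        "patient": manifest.patient,
        "normal_label": manifest.normal_label,
        "lesions": manifest.lesions,
        "params": manifest.params,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_manifest(path) -> Manifest:
    """Load and validate: referenced files must exist, labels must be unique."""
    path = Path(path)
    payload = yaml.safe_load(path.read_text())
    lesions = payload["lesions"]
    labels = [l["label"] for l in lesions]
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate lesion labels {labels}")
    for lesion in lesions:
        for key in ("vcf", "wig"):
            f = path.parent / lesion[key]
            if not f.exists():
                raise FormatError(f"{path}: missing file {f} for lesion {lesion['label']}")
    return Manifest(
        patient=str(payload.get("patient", "synthetic")),
        lesions=lesions,
        normal_label=str(payload.get("normal_label", "normal")),
        params=payload.get("params", {}),
    )


def layout_from_manifest(manifest: Manifest) -> GenomeLayout:
    p = manifest.params
    return GenomeLayout(
        [(str(c), int(l)) for c, l in p["chromosomes"]], int(p["bin_size"])
    )


# ---------------------------------------------------------------- fixtures


def write_fixture(truth, observations, out_dir) -> str:
    """Write a complete simulated paired-lesion fixture; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = truth.layout
    lesions = []
    for label in truth.lesions:
        bins, sites = observations[label]
        vcf = f"{label}.het.vcf"
        wig = f"{label}.logratio.wig"
        write_het_vcf(out / vcf, sites, layout, sample=label)
        write_wig(out / wig, bins, layout)
        lesions.append({"label": label, "vcf": vcf, "wig": wig})

    rows = []
    for label in truth.lesions:
        tree = truth.trees[label]
        for sc in tree.subclones:
            rows.append({
                "lesion": label, "record": "subclone", "subclone": sc.id,
                "prevalence": sc.prevalence, "chrom": "", "start": "", "end": "",
                "c": "", "a": "", "loh_label": "",
            })
        for ev in tree.events:
            rows.append({
                "lesion": label, "record": "event", "subclone": ev.carrier,
                "prevalence": tree.prevalence_of(ev.carrier),
                "chrom": ev.chrom, "start": ev.start, "end": ev.end,
                "c": ev.state.c, "a": ev.state.a, "loh_label": ev.state.loh_label,
            })
    truth_df = pd.DataFrame(rows)
    truth_df.insert(0, "normal_fraction", truth.normal_fraction)
    truth_df.insert(1, "scenario", truth.trees[truth.lesions[0]].scenario)
    truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)

    manifest = Manifest(
        patient="synthetic",
        lesions=lesions,
        normal_label="normal",
        params={
            "chromosomes": [[c, l] for c, l in layout.chromosomes],
            "bin_size": layout.bin_size,
            "normal_fraction": truth.normal_fraction,
            "sigma": truth.sigma,
            "het_depth": truth.het_depth,
            "seed": truth.seed,
            "scenario": truth.trees[truth.lesions[0]].scenario,
        },
    )
    mpath = out / "manifest.yaml"
    write_manifest(mpath, manifest)
    return str(mpath)
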