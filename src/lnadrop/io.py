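"""Readers/writers for the toolkit's table, sequence and config formats.

Canonical dialects: CSV (comma, UTF-8, mandatory header) for instrument-style
inputs (Cq tables, partition tables, endpoint tables); TSV for human-facing
reports; JSON for assay definitions, HDR templates and provenance.  FASTA via
Biopython with IDs preserved verbatim and sequences uppercased; the '+N' LNA
dialect is allowed only in assay sheets, never in FASTA.  Human-facing reports
use 1-based inclusive coordinates; everything in memory is 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .allele_classify import AlleleRecord, FounderSummary, HdrComponent, HdrTemplate
from .assay_design import DropOffAssay
from .dpcr_quant import DpcrChip, DpcrEstimate
from .endpoint_genotype import EndpointSample, GenotypeCall
from .errors import FormatError
from .qpcr_quant import QpcrWell, QuantResult

CQ_COLUMNS = ["sample_id", "channel", "replicate", "cq", "flag"]


# --- FASTA -----------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """(id, uppercased sequence) records; duplicate IDs and empty files error."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate FASTA ids {dupes}")
    return records


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


# --- qPCR Cq tables --------------------------------------------------------------------

def read_cq_table(path) -> list[QpcrWell]:
    """Wells from a Cq CSV with columns sample_id, channel, replicate, cq, flag."""
    df = pd.read_csv(path, dtype={"sample_id": str, "channel": str, "flag": str})
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    wells = []
    errors = []
    for i, row in df.iterrows():
        flags = frozenset() if pd.isna(row["flag"]) or row["flag"] == "" \
            else frozenset(str(row["flag"]).split(";"))
        cq = None if pd.isna(row["cq"]) else float(row["cq"])
        try:
            wells.append(QpcrWell(str(row["sample_id"]), str(row["channel"]),
                                  int(row["replicate"]), cq, flags))
        except Exception as exc:  # collected, not fatal
            errors.append(f"row {i + 2}: {exc}")
    if errors and not wells:
        raise FormatError(f"{path}: no valid rows ({'; '.join(errors[:3])})")
    if errors:
        import warnings

        warnings.warn(f"{path}: skipped {len(errors)} malformed row(s)", stacklevel=2)
    return wells


def write_cq_table(path, wells: list[QpcrWell]) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": w.sample_id,
                "channel": w.channel,
                "replicate": w.replicate,
                "cq": "" if w.cq is None else round(w.cq, 6),
                "flag": ";".join(sorted(w.flags)),
            }
            for w in wells
        ],
        columns=CQ_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_quant_results(path, results: list[QuantResult]) -> None:
    rows = []
    for r in results:
        rows.append({
            "sample_id": r.sample_id,
            "delta_cq": _fmt(r.delta_cq),
            "delta_delta_cq": _fmt(r.delta_delta_cq),
            "wt_percent": _fmt(r.wt_fraction),
            "wt_percent_raw": _fmt(r.wt_fraction_raw),
            "sem_percent": _fmt(r.sem),
            "flags": ";".join(r.flags),
            "error": r.error or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt(x, nd: int = 4) -> str:
    return "" if x is None else f"{x:.{nd}f}"


# --- dPCR partition tables -------------------------------------------------------------

def read_partition_table(path) -> DpcrChip:
    """Chip from a partition CSV: either raw fluorescence (partition_id,
    fluor_ref, fluor_target) or boolean calls (partition_id, ref_positive,
    target_positive)."""
    df = pd.read_csv(path)
    if {"fluor_ref", "fluor_target"} <= set(df.columns):
        fl = df[["fluor_ref", "fluor_target"]].to_numpy(dtype=float)
        return DpcrChip(calls=None, fluorescence=fl)
    if {"ref_positive", "target_positive"} <= set(df.columns):
        calls = df[["ref_positive", "target_positive"]].to_numpy().astype(bool)
        return DpcrChip(calls=calls)
    raise FormatError(
        f"{path}: need columns fluor_ref/fluor_target or ref_positive/target_positive"
    )


def write_partition_table(path, chip: DpcrChip) -> None:
    n = chip.n_total
    data = {"partition_id": np.arange(1, n + 1)}
    if chip.fluorescence is not None:
        data["fluor_ref"] = np.round(chip.fluorescence[:, 0], 5)
        data["fluor_target"] = np.round(chip.fluorescence[:, 1], 5)
    else:
        data["ref_positive"] = chip.calls[:, 0].astype(int)
        data["target_positive"] = chip.calls[:, 1].astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


def write_dpcr_estimate(path, est: DpcrEstimate) -> None:
    c = est.counts
    pd.DataFrame([{
        "lambda_reference": f"{est.lambda_reference:.6f}",
        "lambda_target": f"{est.lambda_target:.6f}",
        "wt_percent": f"{est.wt_fraction:.4f}",
        "wt_percent_raw": f"{est.wt_fraction_raw:.4f}",
        "ci95_low": f"{est.ci95[0]:.4f}",
        "ci95_high": f"{est.ci95[1]:.4f}",
        "double_pos": c.double_pos,
        "ref_only": c.ref_only,
        "target_only": c.target_only,
        "double_neg": c.double_neg,
        "flags": ";".join(est.flags),
    }]).to_csv(path, sep="\t", index=False)


# --- endpoint tables -------------------------------------------------------------------

def read_endpoint_table(path) -> list[EndpointSample]:
    df = pd.read_csv(path, dtype={"sample_id": str, "role": str})
    needed = ["sample_id", "role", "fluor_wt", "fluor_mut"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return [
        EndpointSample(str(r.sample_id), float(r.fluor_wt), float(r.fluor_mut), str(r.role))
        for r in df.itertuples()
    ]


def write_endpoint_table(path, samples: list[EndpointSample]) -> None:
    pd.DataFrame([{
        "sample_id": s.sample_id,
        "role": s.role,
        "fluor_wt": round(s.fluor_wt, 5),
        "fluor_mut": round(s.fluor_mut, 5),
    } for s in samples]).to_csv(path, index=False)


def write_genotype_calls(path, calls: list[GenotypeCall]) -> None:
    pd.DataFrame([{
        "sample_id": c.sample_id,
        "call": c.call,
        "distance": _fmt(c.distance),
        "nearest_control": c.nearest_control or "",
        "amplitude": _fmt(c.amplitude),
        "angle_deg": _fmt(c.angle_deg),
    } for c in calls]).to_csv(path, sep="\t", index=False)


# --- HDR templates and assay definitions ----------------------------------------------

def read_hdr_template(path) -> HdrTemplate:
    with open(path) as fh:
        data = json.load(fh)
    comps = tuple(
        HdrComponent(c["name"], int(c["start"]), c["ref"].upper(), c["alt"].upper())
        for c in data["components"]
    )
    return HdrTemplate(comps, data.get("restriction_site", "GAATTC"))


def write_hdr_template(path, hdr: HdrTemplate) -> None:
    data = {
        "components": [
            {"name": c.name, "start": c.start, "ref": c.ref, "alt": c.alt}
            for c in hdr.components
        ],
        "restriction_site": hdr.restriction_site,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def assay_to_dict(assay: DropOffAssay) -> dict:
    def probe_dict(p):
        return {
            "name": p.name, "sequence": p.sequence, "display": p.display_sequence(),
            "lna_positions": sorted(p.lna_positions), "channel": p.channel,
            "role": p.role, "tm_C": p.tm_C,
            "footprint": list(p.footprint), "strand": p.strand,
        }

    return {
        "reference_id": assay.reference_id,
        "amplicon": list(assay.amplicon),
        "cut_site": assay.cut_site,
        "penalty": assay.penalty,
        "fw_primer": {"sequence": assay.fw_primer.sequence, "tm_C": assay.fw_primer.tm_C,
                      "footprint": list(assay.fw_primer.footprint), "strand": "+"},
        "rv_primer": {"sequence": assay.rv_primer.sequence, "tm_C": assay.rv_primer.tm_C,
                      "footprint": list(assay.rv_primer.footprint), "strand": "-"},
        "target_probe": probe_dict(assay.target_probe),
        "reference_probe": probe_dict(assay.reference_probe),
    }


def write_assay_json(path, assays: list[DropOffAssay]) -> None:
    with open(path, "w") as fh:
        json.dump([assay_to_dict(a) for a in assays], fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_assay_sheet(path, assays: list[DropOffAssay]) -> None:
    """One row per oligo: name, sequence ('+N' marks a locked base), channel,
    Tm, 1-based inclusive coordinates."""
    rows = []
    for i, a in enumerate(assays, 1):
        oligos = [
            (a.fw_primer.name, a.fw_primer.sequence, "", a.fw_primer.tm_C,
             a.fw_primer.footprint, "+"),
            (a.rv_primer.name, a.rv_primer.sequence, "", a.rv_primer.tm_C,
             a.rv_primer.footprint, "-"),
            (a.target_probe.name, a.target_probe.display_sequence(),
             a.target_probe.channel, a.target_probe.tm_C, a.target_probe.footprint, "+"),
            (a.reference_probe.name, a.reference_probe.display_sequence(),
             a.reference_probe.channel, a.reference_probe.tm_C,
             a.reference_probe.footprint, "+"),
        ]
        for name, seq, channel, tm, fp, strand in oligos:
            rows.append({
                "assay": f"assay{i}", "oligo": name, "sequence": seq,
                "channel": channel, "tm_C": tm,
                "start_1based": fp[0] + 1, "end_1based": fp[1], "strand": strand,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- classification reports ------------------------------------------------------------

def write_clone_report(path, records: list[AlleleRecord]) -> None:
    """Per-clone TSV; variants in a POS,REF,ALT,TYPE mini-format (1-based POS)."""
    rows = []
    for r in records:
        variants = ";".join(
            f"{v.pos + 1},{v.ref or '-'},{v.alt or '-'},{v.kind}"
            for v in r.variants_in_window
        )
        outside = ";".join(
            f"{v.pos + 1},{v.ref or '-'},{v.alt or '-'},{v.kind}"
            for v in r.variants_outside_window
        )
        rows.append({
            "clone_id": r.clone_id,
            "category": r.category,
            "hdr_components": ";".join(sorted(r.hdr_components_present)),
            "variants": variants,
            "variants_outside_window": outside,
            "identity": f"{r.identity:.4f}",
            "orientation": r.orientation,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_founder_summaries(path, summaries: list[FounderSummary]) -> None:
    rows = []
    for s in summaries:
        row = {
            "animal_id": s.animal_id,
            "n_clones": s.n_clones,
            "distinct_alleles": s.distinct_alleles,
            "wt_percent": f"{s.wt_percent:.4f}",
            "variants_outside_window": s.n_variants_outside_window,
        }
        for cat, frac in sorted(s.category_fractions.items()):
            row[f"frac_{cat}"] = f"{frac:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_venn_counts(path, cells: dict[frozenset[str], int]) -> None:
    rows = [
        {"components": "+".join(sorted(subset)), "n": n}
        for subset, n in sorted(cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- provenance ------------------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, subcommand: str, config: dict, inputs: list) -> None:
    """Machine-readable run record: inputs hashed, full config echo, versions,
    seed.  No timestamps, so identical runs produce identical files."""
    doc = {
        "tool": "lnadrop",
        "version": __version__,
        "subcommand": subcommand,
        "config": config,
        "inputs": {str(Path(p).name): sha256_file(p) for p in sorted(map(str, inputs))},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
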