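"""End-to-end orchestration of the morphometric and sequence analyses."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

from odobenus import asymmetry as asym
from odobenus import differentiation as diff
from odobenus import diversity as div
from odobenus import io as oio
from odobenus import mjnetwork as mjn
from odobenus.config import PipelineConfig

log = logging.getLogger("odobenus")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _largest_regions(regions_with_sizes: dict[str, int], minimum: int) -> list[str]:
    eligible = [r for r, n in regions_with_sizes.items() if n >= minimum]
    return sorted(eligible, key=lambda r: -regions_with_sizes[r])[:2]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns (and writes) the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    inputs: dict[str, str] = {}

    def emit(name: str, rows) -> Path:
        path = out_dir / name
        oio.write_results_table(rows, path)
        outputs.append(str(path))
        return path

    if config.morpho_csv:
        try:
            ds = oio.read_morpho_table(config.morpho_csv)
        except (OSError, oio.DataError) as exc:
            raise PipelineError("read_morpho", f"{config.morpho_csv}: {exc}") from exc
        inputs[str(config.morpho_csv)] = _sha256(config.morpho_csv)
        log.info("morphometrics: %d specimens, regions %s", len(ds), ds.regions)
        _run_morpho(ds, config, emit)

    if config.fasta:
        try:
            aln = oio.read_alignment(config.fasta, config.metadata_csv)
        except (OSError, oio.DataError) as exc:
            raise PipelineError("read_alignment", f"{config.fasta}: {exc}") from exc
        inputs[str(config.fasta)] = _sha256(config.fasta)
        inputs[str(config.metadata_csv)] = _sha256(config.metadata_csv)
        log.info("sequences: %d samples of length %d", len(aln), aln.length)
        _run_sequences(aln, config, emit, out_dir, outputs)

    from odobenus import __version__

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": inputs,
        "outputs": outputs,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("wrote %d output files to %s", len(outputs), out_dir)
    return manifest


def _run_morpho(ds, config: PipelineConfig, emit) -> None:
    sizes = {r: len(ds.subset(r)) for r in ds.regions}
    main_pair = _largest_regions(sizes, max(config.min_group_size, 2))
    if len(main_pair) < 2:
        raise PipelineError("asymmetry", "need two regions with enough specimens")
    a, b = main_pair

    # side regressions and asymmetry tables
    reg_rows = []
    for code in oio.BILATERAL_CODES:
        try:
            r = asym.regress_sides(ds, code)
        except oio.DataError:
            continue
        reg_rows.append(asdict(r))
    emit("side_regressions.csv", reg_rows)

    table = asym.asymmetry_table(ds)
    by_key = {(row.measure_code, row.region): row for row in table}
    asym_rows = []
    for code in oio.BILATERAL_CODES:
        row_a, row_b = by_key.get((code, a)), by_key.get((code, b))
        if row_a is None or row_b is None:
            continue
        record = {"measure": code}
        for label, family in (("da", "pct_da_values"), ("aa", "pct_aa_values")):
            try:
                cmp = asym.compare_asymmetry(
                    getattr(row_a, family),
                    getattr(row_b, family),
                    measure_code=code,
                    alpha=config.alpha,
                    m_tests=config.bonferroni_m,
                )
            except oio.DataError:
                continue
            record.update(
                {
                    f"{label}_{a}": getattr(row_a, f"mean_pct_{label}"),
                    f"{label}_{b}": getattr(row_b, f"mean_pct_{label}"),
                    f"{label}_t": cmp.statistic,
                    f"{label}_p": cmp.p_value,
                    f"{label}_significant": cmp.significant_bonferroni,
                }
            )
        asym_rows.append(record)
    emit("asymmetry.csv", asym_rows)

    # standardization + univariate + DAPC per block
    mat = diff.standardize(ds)
    uni_rows = [asdict(c) for c in diff.compare_groups(mat, a, b, config.alpha)]
    emit("univariate.csv", uni_rows)

    pca_rows, dfa_rows = [], []
    for block in diff.BLOCKS:
        sub = mat.block(block)
        try:
            p = diff.pca(sub, scaling=config.pca_scaling)
            d = diff.dfa(
                p.scores,
                mat.regions,
                n_components=config.dfa_variance_threshold,
                proportions=p.proportions,
                min_group_size=2,
            )
        except oio.DataError as exc:
            log.warning("block %s skipped: %s", block, exc)
            continue
        for i, (ev, prop) in enumerate(zip(p.eigenvalues, p.proportions)):
            pca_rows.append(
                {"block": block, "component": i + 1, "eigenvalue": ev, "proportion": prop}
            )
        isolated, overlap = diff.assess_isolation(d, (a, b))
        for sid in d.scores.index:
            dfa_rows.append(
                {
                    "block": block,
                    "specimen_id": sid,
                    "region": d.groups.loc[sid],
                    "ld1": d.scores.loc[sid, "LD1"],
                    "ld2": d.scores.loc[sid, "LD2"] if "LD2" in d.scores else "",
                    "isolated_pair": f"{a}-{b}",
                    "isolated": isolated,
                    "overlap": overlap,
                }
            )
    emit("pca_variance.csv", pca_rows)
    emit("dfa_scores.csv", dfa_rows)


def _run_sequences(aln, config: PipelineConfig, emit, out_dir: Path, outputs: list) -> None:
    ht = div.collapse_haplotypes(aln, truncate_to=config.truncate_to)
    hap_rows = []
    for hid, seq in ht.haplotypes:
        row = {"hap_id": hid, "sequence": seq}
        for region in ht.regions:
            row[f"n_{region}"] = ht.region_counts(region).get(hid, 0)
        hap_rows.append(row)
    emit("haplotypes.csv", hap_rows)

    stats_rows, divergence = div.diversity_report(ht)
    emit("diversity.csv", [asdict(s) for s in stats_rows])
    emit(
        "divergence.csv",
        [
            {"region_a": p[0], "region_b": p[1], "k": k}
            for p, k in sorted(divergence.values.items())
        ],
    )

    net = mjn.build_mj_network(ht, epsilon=config.epsilon)
    graphml = out_dir / "network.graphml"
    mjn.export_network(net, graphml, "graphml")
    outputs.append(str(graphml))
    edges = out_dir / "network_edges.csv"
    mjn.export_network(net, edges, "edge_list_csv")
    outputs.append(str(edges))
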