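"""End-to-end wiring: load/simulate → similarity layers → CV/prediction.

`build_similarities` performs the network-construction stage: topological
GIP layers from the association matrices, entropy fusion with the supplied
semantic layers, and the two drug similarity layers.  `run_pipeline`
executes the full four-stage pipeline from a :class:`RunConfig` and writes
a run manifest (config echo, seeds, package version, output checksums)
alongside the outputs so every artifact is reproducible from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .model_cv import CVConfig, ForestParams, run_cv
from .netio import (
    HeterogeneousNetwork,
    SimilarityMatrix,
    network_summary,
    read_edge_list,
    read_id_list,
    read_similarity_matrix,
    write_edge_list,
    write_similarity_matrix,
)
from .similarity import GipParams, entropy_fuse, gip_similarity
from .synthetic import SyntheticConfig, SyntheticNetwork, generate_network

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "build_similarities",
    "load_network_dir",
    "write_network_dir",
    "run_pipeline",
]

NETWORK_FILES = {
    "targets": "targets.txt",
    "diseases": "diseases.txt",
    "drugs": "drugs.txt",
    "tda": "tda.tsv",
    "tdi": "tdi.tsv",
    "dda": "dda.tsv",
    "tts_s": "tts_s.tsv",
    "dds_s": "dds_s.tsv",
}


def build_similarities(
    net: HeterogeneousNetwork,
    tts_s: SimilarityMatrix,
    dds_s: SimilarityMatrix,
    gip: GipParams = GipParams(),
) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Network-construction stage: (TTS, DDS, MMS_T, MMS_D).

    Target and disease topological similarities come from the GIP kernel on
    the rows/columns of the target–disease matrix and are entropy-fused with
    the semantic layers; the two drug layers are pure GIP on the target–drug
    and disease–drug columns.
    """
    tts_t = gip_similarity(net.tda, axis="rows", params=gip)
    dds_t = gip_similarity(net.tda, axis="columns", params=gip)
    tts = entropy_fuse(tts_s, tts_t)
    dds = entropy_fuse(dds_s, dds_t)
    mms_t = gip_similarity(net.tdi, axis="columns", params=gip)
    mms_d = gip_similarity(net.dda, axis="columns", params=gip)
    return tts, dds, mms_t, mms_d


def load_network_dir(
    directory: str | Path,
) -> tuple[HeterogeneousNetwork, SimilarityMatrix, SimilarityMatrix]:
    """Load a network directory written by :func:`write_network_dir`."""
    d = Path(directory)
    for name in NETWORK_FILES.values():
        if not (d / name).exists():
            raise FileNotFoundError(f"missing input file {d / name}")
    targets = read_id_list(d / NETWORK_FILES["targets"], "target")
    diseases = read_id_list(d / NETWORK_FILES["diseases"], "disease")
    drugs = read_id_list(d / NETWORK_FILES["drugs"], "drug")
    net = HeterogeneousNetwork(
        targets=targets,
        diseases=diseases,
        drugs=drugs,
        tda=read_edge_list(d / NETWORK_FILES["tda"], targets, diseases),
        tdi=read_edge_list(d / NETWORK_FILES["tdi"], targets, drugs),
        dda=read_edge_list(d / NETWORK_FILES["dda"], diseases, drugs),
    )
    tts_s = read_similarity_matrix(d / NETWORK_FILES["tts_s"], targets)
    dds_s = read_similarity_matrix(d / NETWORK_FILES["dds_s"], diseases)
    return net, tts_s, dds_s


def write_network_dir(directory: str | Path, sn: SyntheticNetwork) -> None:
    """Write a synthetic network in the TSV formats the readers consume."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    net = sn.network
    for name, reg in [
        ("targets", net.targets), ("diseases", net.diseases), ("drugs", net.drugs)
    ]:
        (d / NETWORK_FILES[name]).write_text(
            "\n".join(reg.ids) + "\n", encoding="utf-8"
        )
    write_edge_list(d / NETWORK_FILES["tda"], net.tda)
    write_edge_list(d / NETWORK_FILES["tdi"], net.tdi)
    write_edge_list(d / NETWORK_FILES["dda"], net.dda)
    write_similarity_matrix(d / NETWORK_FILES["tts_s"], sn.tts_s)
    write_similarity_matrix(d / NETWORK_FILES["dds_s"], sn.dds_s)
    with open(d / "categories.tsv", "w", encoding="utf-8") as fh:
        fh.write("# disease_id\tcategory_code\n")
        for did in net.diseases.ids:
            for code in sorted(sn.categories.mapping.get(did, ())):
                fh.write(f"{did}\t{code}\n")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``network_dir`` (existing TSV inputs) or ``synthetic`` (generate
    inputs) must be set.
    """

    output_dir: str
    network_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    gip: GipParams = field(default_factory=GipParams)
    forest: ForestParams = field(default_factory=ForestParams)
    cv: CVConfig = field(default_factory=CVConfig)
    feature_subset: tuple | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.network_dir is None) == (self.synthetic is None):
            raise ValueError("set exactly one of network_dir or synthetic")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute set construction → network construction → features+CV.

    Writes ``cv_result.json`` and ``manifest.json`` into the output
    directory and returns the manifest.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/4: set construction")
    if cfg.synthetic is not None:
        sn = generate_network(cfg.synthetic)
        net, tts_s, dds_s = sn.network, sn.tts_s, sn.dds_s
    else:
        net, tts_s, dds_s = load_network_dir(cfg.network_dir)
    summary = network_summary(net)
    logger.info("network summary:\n%s", summary)

    logger.info("stage 2/4: network construction (GIP + entropy fusion)")
    tts, dds, mms_t, mms_d = build_similarities(net, tts_s, dds_s, cfg.gip)

    n_pos = net.tda.n_edges
    n_unconfirmed = net.tda.size - n_pos
    logger.info(
        "stage 3/4 + 4/4: features, training and cross-validation "
        "(%d positives, %d negatives, %d unlabeled)",
        n_pos, n_pos, n_unconfirmed - n_pos,
    )
    result = run_cv(
        net, tts, dds, mms_t, mms_d, cfg.cv, cfg.forest,
        feature_subset=cfg.feature_subset,
        tts_s=tts_s, dds_s=dds_s,
    )
    result_path = out / "cv_result.json"
    result_path.write_text(json.dumps(result.to_dict(), indent=2))
    summary_path = out / "network_summary.tsv"
    summary.to_csv(summary_path, sep="\t")

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "outputs": {
            p.name: _sha256(p) for p in (result_path, summary_path)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
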