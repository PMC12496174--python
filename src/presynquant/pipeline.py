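"""End-to-end localization pipeline: axon -> clusters -> NN -> membership.

Every output table carries the SHA-256 hash of the run configuration in a
comment header so results are traceable to their parameters; reruns with
the same seed and configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axon import AxonResult, AxonSegmentationParams, segment_axon
from .colocalization import (
    DEFAULT_SYNAPSE_RADIUS_NM,
    classify_membership,
    nn_distances,
    nn_histogram,
)
from .imaging import ImageStack, read_tiff
from .puncta import ClusterParams, ClusterSet, segment_clusters
from .simulate import AXON_CHANNEL, SimulationConfig, generate_axon_scene

__all__ = ["RunConfig", "PipelineReport", "run_localization_pipeline", "write_table"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """Failure inside a named pipeline stage (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Configuration of one localization run.

    Either ``image_path`` (multi-page TIFF) or ``simulation`` (generator
    settings) provides the input stack. ``axon_channel`` names the marker
    used for axon segmentation; ``cluster_channels`` the channels to segment
    into puncta; ``reference_channel`` the set NN distances are measured
    against (and membership classified around).
    """

    image_path: str | None = None
    simulation: dict | None = None
    axon_channel: str = AXON_CHANNEL
    cluster_channels: list[str] = field(default_factory=lambda: ["cluster_a", "cluster_b"])
    reference_channel: str = "cluster_b"
    pixel_size_nm: float | None = None
    manual_roi_path: str | None = None
    axon_params: dict = field(default_factory=dict)
    cluster_params: dict = field(default_factory=dict)
    membership_radius_nm: float = DEFAULT_SYNAPSE_RADIUS_NM
    histogram_bin_nm: float = 50.0
    seed: int = 0
    output_dir: str = "presynquant_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineReport:
    axon: AxonResult
    cluster_sets: dict[str, ClusterSet]
    nn_tables: dict[str, pd.DataFrame]
    histograms: dict[str, pd.DataFrame]
    membership: dict[str, dict]
    provenance: dict


def write_table(df: pd.DataFrame, path, config_hash: str) -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_stack(config: RunConfig) -> ImageStack:
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
        stack, _ = generate_axon_scene(sim)
        return stack
    if config.image_path is None:
        raise ConfigError("either image_path or simulation must be set")
    return read_tiff(config.image_path, pixel_size_nm=config.pixel_size_nm)


def run_localization_pipeline(config: RunConfig, output_dir=None) -> PipelineReport:
    """Run axon segmentation, cluster segmentation, NN analysis and synapse
    membership for one image; optionally write all tables under
    ``output_dir``. Empty segmentations propagate as empty tables."""
    chash = config.config_hash()
    stack = _load_stack(config)

    try:
        manual_roi = None
        if config.manual_roi_path:
            from .imaging import read_roi_labels

            manual_roi = read_roi_labels(config.manual_roi_path) > 0
        axon = segment_axon(
            stack.channel(config.axon_channel),
            AxonSegmentationParams(**config.axon_params),
            manual_roi=manual_roi,
        )
    except KeyError as exc:
        raise ConfigError(f"axon channel missing: {exc}") from exc
    except Exception as exc:  # noqa: BLE001 - stage-named reporting contract
        raise StageError(f"axon_segmentation: {exc}") from exc

    cluster_sets: dict[str, ClusterSet] = {}
    for name in config.cluster_channels:
        try:
            cluster_sets[name] = segment_clusters(
                stack.channel(name), ClusterParams(**config.cluster_params), axon
            )
        except KeyError as exc:
            raise ConfigError(f"cluster channel missing: {exc}") from exc
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"puncta_segmentation[{name}]: {exc}") from exc

    reference = cluster_sets.get(config.reference_channel)
    if reference is None:
        raise ConfigError(f"reference channel {config.reference_channel!r} not segmented")

    nn_tables, histograms, membership = {}, {}, {}
    for name, cs in cluster_sets.items():
        if name == config.reference_channel:
            continue
        try:
            if len(reference.centroids_nm()) == 0 or len(cs.centroids_nm()) == 0:
                nn_tables[name] = pd.DataFrame(columns=["nn_distance_nm", "target_index"])
                histograms[name] = pd.DataFrame(columns=["bin_left_nm", "bin_right_nm", "count"])
                membership[name] = {"fraction_within": 0.0, "n": 0}
                continue
            nn = nn_distances(cs, reference)
            counts, edges, mode = nn_histogram(nn, config.histogram_bin_nm)
            member = classify_membership(cs, reference, config.membership_radius_nm)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"colocalization[{name}]: {exc}") from exc
        nn_tables[name] = nn.to_dataframe()
        histograms[name] = pd.DataFrame(
            {"bin_left_nm": edges[:-1], "bin_right_nm": edges[1:], "count": counts}
        )
        membership[name] = {
            "fraction_within": member.fraction_within,
            "n": int(member.within.size),
            "modal_nn_bin_center_nm": mode,
        }

    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "axon_source": axon.source,
        "n_clusters": {k: len(v) for k, v in cluster_sets.items()},
    }
    report = PipelineReport(axon, cluster_sets, nn_tables, histograms, membership, provenance)

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .imaging import PixelImage, write_tiff

        write_tiff(
            ImageStack(
                [
                    PixelImage(axon.mask.astype(np.uint8), stack.pixel_size_nm, "axon_mask"),
                    PixelImage(axon.skeleton.astype(np.uint8), stack.pixel_size_nm, "skeleton"),
                ]
            ),
            out / "axon.tif",
        )
        for name, cs in cluster_sets.items():
            write_table(cs.to_dataframe(), out / f"clusters_{name}.tsv", chash)
        for name in nn_tables:
            write_table(nn_tables[name], out / f"nn_{name}.tsv", chash)
            write_table(histograms[name], out / f"nn_hist_{name}.tsv", chash)
        summary = pd.DataFrame(
            [{"channel": k, **v} for k, v in membership.items()]
        )
        write_table(summary, out / "membership.tsv", chash)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return report
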