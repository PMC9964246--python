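"""Study configuration: group distribution parameters, contact geometry,
failure constants, seed and output options, with YAML/JSON round-trip.

``default_study_config`` carries the study conditions: two groups of 20
females (healthy weight, BMI < 25 kg/m^2; obese, BMI > 30 kg/m^2) with the
published group means/SDs for anthropometrics, gait spatiotemporals and net
peak medial tibiofemoral force, the default contact geometry and the default
failure constants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import GroupSpec, WaveformShape
from .contact import ContactGeometry
from .failure import FailureParams


def healthy_weight_spec(n: int = 20, enforce_exact_means: bool = False) -> GroupSpec:
    return GroupSpec(
        label="healthy_weight",
        n=n,
        mass_mean=63.18, mass_sd=3.55,
        stature_mean=1.63, stature_sd=0.05,
        velocity_mean=1.45, velocity_sd=0.24,
        stride_length_mean=1.61, stride_length_sd=0.21,
        peak_force_n_mean=1493.21, peak_force_n_sd=370.19,
        vasti_bw_means=(0.56, 0.49, 0.42),
        vasti_bw_sds=(0.25, 0.22, 0.19),
        bmi_mean=23.71,
        bmi_bounds=(15.0, 25.0),
        enforce_exact_means=enforce_exact_means,
    )


def obese_spec(n: int = 20, enforce_exact_means: bool = False) -> GroupSpec:
    return GroupSpec(
        label="obese",
        n=n,
        mass_mean=92.82, mass_sd=5.59,
        stature_mean=1.63, stature_sd=0.05,
        velocity_mean=1.38, velocity_sd=0.21,
        stride_length_mean=1.55, stride_length_sd=0.18,
        peak_force_n_mean=2013.92, peak_force_n_sd=570.91,
        vasti_bw_means=(0.57, 0.50, 0.42),
        vasti_bw_sds=(0.19, 0.17, 0.15),
        bmi_mean=34.87,
        bmi_bounds=(30.0, 55.0),
        enforce_exact_means=enforce_exact_means,
    )


@dataclass
class StudyConfig:
    healthy: GroupSpec
    obese: GroupSpec
    geometry: ContactGeometry = field(default_factory=ContactGeometry)
    failure: FailureParams = field(default_factory=FailureParams)
    seed: int = 0
    output_dir: str = "results"
    write_waveforms: bool = False
    sensitivity_ranges: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.healthy.validate()
        self.obese.validate()
        self.geometry.validate()
        self.failure.validate()
        if self.seed is None:
            raise ValueError("a seed is required (no silent nondeterminism)")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("healthy", "obese"):
            for fld in ("vasti_bw_means", "vasti_bw_sds", "bmi_bounds"):
                d[key][fld] = list(d[key][fld])
            wf = d[key]["waveform"]
            for fld in ("bump_times", "bump_widths", "bump_weights"):
                wf[fld] = list(wf[fld])
        d["geometry"]["footprint"] = list(d["geometry"]["footprint"])
        d["sensitivity_ranges"] = {
            k: [float(v) for v in vs] for k, vs in d["sensitivity_ranges"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        def group(sub: dict) -> GroupSpec:
            sub = dict(sub)
            wf = sub.pop("waveform", None)
            for fld in ("vasti_bw_means", "vasti_bw_sds", "bmi_bounds"):
                if fld in sub:
                    sub[fld] = tuple(sub[fld])
            spec = GroupSpec(**sub)
            if wf:
                wf = dict(wf)
                for fld in ("bump_times", "bump_widths", "bump_weights"):
                    if fld in wf:
                        wf[fld] = tuple(wf[fld])
                spec.waveform = WaveformShape(**wf)
            return spec

        geo = dict(d.get("geometry", {}))
        if "footprint" in geo:
            geo["footprint"] = tuple(geo["footprint"])
        return cls(
            healthy=group(d["healthy"]),
            obese=group(d["obese"]),
            geometry=ContactGeometry(**geo),
            failure=FailureParams(**d.get("failure", {})),
            seed=d.get("seed", 0),
            output_dir=d.get("output_dir", "results"),
            write_waveforms=d.get("write_waveforms", False),
            sensitivity_ranges=d.get("sensitivity_ranges", {}),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)


def default_study_config(
    seed: int = 0, n_per_group: int = 20, enforce_exact_means: bool = False
) -> StudyConfig:
    return StudyConfig(
        healthy=healthy_weight_spec(n_per_group, enforce_exact_means),
        obese=obese_spec(n_per_group, enforce_exact_means),
        seed=seed,
    )
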