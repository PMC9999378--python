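"""Synthetic stance-phase gait loading and load-instance selection.

Emulates the output of musculoskeletal gait simulations: a hip contact
force (HCF) waveform with the characteristic double peak during stance,
plus a small set of muscle point loads with attachment sites on the femur.
From a set of trials the representative trial (lowest RMS difference to
the mean waveform) is picked and nine load instances are extracted around
the two HCF peaks and the valley in between.

All forces are in newtons in the femur frame (X anterior, Y proximal,
Z lateral for a right femur); stance is normalized to 0-100%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from gpfem._util import unit

GRAVITY = 9.81
#: reference body mass (kg) the nominal muscle strengths are defined at
GENERIC_BODY_MASS = 36.8


def scale_muscle_strength(f_generic: float, m_scaled: float, m_generic: float) -> float:
    """Scale a muscle force by the 2/3 power of the body-mass ratio."""
    if m_scaled <= 0 or m_generic <= 0:
        raise ValueError("body masses must be positive")
    return float(f_generic * (m_scaled / m_generic) ** (2.0 / 3.0))


@dataclass
class Muscle:
    name: str
    attachment: np.ndarray  # (3,) mm
    direction: np.ndarray  # (T, 3) unit vectors
    magnitude: np.ndarray  # (T,) N, >= 0

    def force(self, idx=None) -> np.ndarray:
        if idx is None:
            return self.direction * self.magnitude[:, None]
        return self.direction[idx] * self.magnitude[idx]


@dataclass
class GaitTrial:
    stance_pct: np.ndarray  # (T,), 0..100
    hcf: np.ndarray  # (T, 3) N
    muscles: list = field(default_factory=list)
    body_mass: float = GENERIC_BODY_MASS
    profile: str = "TD"

    def __post_init__(self):
        self.stance_pct = np.asarray(self.stance_pct, float)
        self.hcf = np.asarray(self.hcf, float)
        if self.hcf.shape != (self.stance_pct.size, 3):
            raise ValueError("hcf must be (T, 3) matching the stance grid")
        for m in self.muscles:
            norms = np.linalg.norm(m.direction, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError(f"muscle {m.name}: directions must be unit vectors")
            if np.any(m.magnitude < 0):
                raise ValueError(f"muscle {m.name}: magnitudes must be >= 0")

    @property
    def resultant(self) -> np.ndarray:
        return np.linalg.norm(self.hcf, axis=1)


@dataclass
class LoadInstance:
    instance_id: int  # 1..9
    stance_pct: float
    hcf_vector: np.ndarray  # (3,) N
    muscle_point_loads: list  # [(name, point(3,), force(3,))]

    @property
    def total_force(self) -> np.ndarray:
        total = np.array(self.hcf_vector, float)
        for _, _, f in self.muscle_point_loads:
            total = total + f
        return total


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

#: stance-phase HCF waveform parameters per profile: peak/valley levels in
#: body weights (mean, sd) and peak timing jitter (sd, % stance)
HCF_PROFILES = {
    "TD": dict(p1=(4.0, 0.20), p2=(4.2, 0.20), valley=(2.6, 0.15), t_sd=1.5),
    "CP": dict(p1=(3.7, 0.45), p2=(3.9, 0.45), valley=(2.5, 0.35), t_sd=3.5),
}

#: nominal muscle set: attachment site (symbolic), peak force in N at the
#: reference body mass, activation bump center/width in % stance
MUSCLE_TABLE = [
    ("gluteus_medius", "greater_trochanter", 700.0, (30.0, 28.0)),
    ("gluteus_maximus", "posterior_proximal", 420.0, (20.0, 22.0)),
    ("psoas", "lesser_trochanter", 380.0, (85.0, 20.0)),
    ("adductor_magnus", "medial_shaft", 300.0, (55.0, 30.0)),
    ("vastus_lateralis", "anterior_proximal", 500.0, (25.0, 24.0)),
]


def _attachment_sites(femur) -> dict:
    """Muscle attachment coordinates derived from femur metadata."""
    meta, frame = femur.meta, femur.frame
    p0 = meta["p0"]
    prox = frame["proximal"]
    lat = frame["lateral"]
    ant = frame["anterior"]
    r = femur.params.shaft_outer_radius if femur.params else 11.0
    return dict(
        greater_trochanter=p0 + 2.0 * prox + 1.15 * r * lat,
        posterior_proximal=p0 - 6.0 * prox - 1.0 * r * ant + 0.3 * r * lat,
        lesser_trochanter=p0 - 10.0 * prox - 0.7 * r * ant - 0.9 * r * lat,
        medial_shaft=p0 - 35.0 * prox - 1.0 * r * lat,
        anterior_proximal=p0 - 15.0 * prox + 1.0 * r * ant + 0.4 * r * lat,
    )


def _muscle_pull_directions(frame) -> dict:
    prox, lat, ant = frame["proximal"], frame["lateral"], frame["anterior"]
    return dict(
        greater_trochanter=unit(0.9 * prox - 0.45 * lat + 0.05 * ant),
        posterior_proximal=unit(0.8 * prox - 0.5 * ant - 0.2 * lat),
        lesser_trochanter=unit(0.75 * prox + 0.55 * ant - 0.3 * lat),
        medial_shaft=unit(0.85 * prox - 0.5 * lat),
        anterior_proximal=unit(-0.95 * prox + 0.25 * lat),
    )


def _hcf_direction(nsa_deg: float, ava_deg: float, frame: dict, t: np.ndarray) -> np.ndarray:
    """Unit HCF direction over stance: mostly distal, tilted toward the
    neck axis, with a small anterior->posterior sweep."""
    beta = np.radians(180.0 - nsa_deg)
    alpha = np.radians(ava_deg)
    prox, lat, ant = frame["proximal"], frame["lateral"], frame["anterior"]
    neck = (
        np.sin(beta) * np.sin(alpha) * ant
        + np.cos(beta) * prox
        - np.sin(beta) * np.cos(alpha) * lat
    )
    base = -unit(0.65 * prox + 0.35 * neck)
    sweep = 0.12 * np.cos(np.pi * t / 100.0)
    dirs = base[None, :] + sweep[:, None] * ant[None, :]
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def synthesize_trials(
    profile: str,
    n_trials: int,
    body_mass: float,
    seed: int,
    femur=None,
    nsa_deg: float | None = None,
    ava_deg: float | None = None,
    n_samples: int = 101,
) -> list:
    """Generate stance-phase gait trials for one femur.

    Each trial's HCF resultant is a monotone-segment (PCHIP) waveform
    through jittered control points, which guarantees exactly two strict
    local maxima with one interior valley.  Peak magnitudes stay within
    2-6 body weights.  The CP profile uses larger inter-trial jitter than
    TD.  ``nsa_deg``/``ava_deg`` orient the HCF (defaults: the femur's own
    geometry -- the "personalized" loading variant; pass reference angles
    for a "generic" variant).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if profile not in HCF_PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    from gpfem.femur import FemurParams, generate_femur

    if femur is None:
        femur = generate_femur(FemurParams())
    if nsa_deg is None:
        nsa_deg = femur.params.nsa_deg if femur.params else 133.0
    if ava_deg is None:
        ava_deg = femur.params.ava_deg if femur.params else 20.0

    cfg = HCF_PROFILES[profile]
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 100.0, n_samples)
    bw = body_mass * GRAVITY
    sites = _attachment_sites(femur)
    pulls = _muscle_pull_directions(femur.frame)
    strength = scale_muscle_strength(1.0, body_mass, GENERIC_BODY_MASS)

    trials = []
    for _ in range(n_trials):
        t1 = np.clip(25.0 + cfg["t_sd"] * rng.standard_normal(), 15.0, 38.0)
        t2 = np.clip(75.0 + cfg["t_sd"] * rng.standard_normal(), 62.0, 88.0)
        p1 = np.clip(rng.normal(*cfg["p1"]), 2.2, 5.8)
        p2 = np.clip(rng.normal(*cfg["p2"]), 2.2, 5.8)
        v = np.clip(rng.normal(*cfg["valley"]), 1.0, min(p1, p2) - 0.4)
        knots = np.array([0.0, t1, 50.0, t2, 100.0])
        levels = bw * np.array([0.45, p1, v, p2, 0.15])
        resultant = PchipInterpolator(knots, levels)(t)
        dirs = _hcf_direction(nsa_deg, ava_deg, femur.frame, t)
        hcf = dirs * resultant[:, None]

        muscles = []
        for name, site, peak_n, (center, width) in MUSCLE_TABLE:
            c = center + 0.6 * cfg["t_sd"] * rng.standard_normal()
            peak = max(0.0, peak_n * strength * (1.0 + 0.08 * rng.standard_normal()))
            bump = np.exp(-0.5 * ((t - c) / (width / 2.355)) ** 2)
            mag = peak * (0.12 + 0.88 * bump)
            direction = np.tile(pulls[site], (n_samples, 1))
            muscles.append(
                Muscle(name=name, attachment=np.array(sites[site], float),
                       direction=direction, magnitude=mag)
            )
        trials.append(
            GaitTrial(stance_pct=t.copy(), hcf=hcf, muscles=muscles,
                      body_mass=body_mass, profile=profile)
        )
    return trials


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def select_representative_trial(trials: list) -> int:
    """Index of the trial whose HCF resultant is closest (RMS) to the mean
    waveform over all trials; ties break to the lowest index."""
    if len(trials) == 0:
        raise ValueError("no trials given")
    grids = [np.asarray(tr.stance_pct) for tr in trials]
    if any(g.shape != grids[0].shape or not np.allclose(g, grids[0]) for g in grids):
        raise ValueError("trials are not sampled on a common stance grid")
    resultants = np.stack([tr.resultant for tr in trials])
    mean = resultants.mean(axis=0)
    rms = np.sqrt(np.mean((resultants - mean) ** 2, axis=1))
    return int(np.argmin(rms))


def _strict_local_maxima(y: np.ndarray) -> np.ndarray:
    return np.where((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1


def find_hcf_peaks(trial: GaitTrial, smooth_width: int = 3):
    """Indices of the two dominant HCF peaks and the interior valley.

    Peaks are strict local maxima of the lightly smoothed resultant; when
    more than two exist the two largest are used.
    """
    y = trial.resultant
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        ys = np.convolve(y, kernel, mode="same")
    else:
        ys = y
    peaks = _strict_local_maxima(ys)
    if len(peaks) < 2:
        raise ValueError(
            "HCF resultant waveform has fewer than 2 interior local maxima; "
            "cannot select load instances"
        )
    if len(peaks) > 2:
        peaks = peaks[np.argsort(ys[peaks])[-2:]]
    i1, i2 = int(min(peaks)), int(max(peaks))
    valley = i1 + int(np.argmin(y[i1 : i2 + 1]))
    return i1, valley, i2


def select_load_instances(trial: GaitTrial, n_between: int = 3, smooth_width: int = 3) -> list:
    """Nine load instances: the two HCF peaks, the valley in between, and
    ``n_between`` equally spaced stance points inside each half.

    Muscle forces are read (linearly interpolated) at the same stance
    percentages as the HCF.
    """
    i1, iv, i2 = find_hcf_peaks(trial, smooth_width=smooth_width)
    t = trial.stance_pct
    first = np.linspace(t[i1], t[iv], n_between + 2)
    second = np.linspace(t[iv], t[i2], n_between + 2)
    pcts = np.concatenate([first, second[1:]])

    instances = []
    for k, pct in enumerate(pcts, start=1):
        hcf = np.array([np.interp(pct, t, trial.hcf[:, j]) for j in range(3)])
        loads = []
        for m in trial.muscles:
            mag = np.interp(pct, t, m.magnitude)
            d = np.array([np.interp(pct, t, m.direction[:, j]) for j in range(3)])
            d = unit(d)
            loads.append((m.name, np.array(m.attachment, float), d * mag))
        instances.append(
            LoadInstance(instance_id=k, stance_pct=float(pct),
                         hcf_vector=hcf, muscle_point_loads=loads)
        )
    return instances


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def trial_to_csv(trial: GaitTrial, path) -> None:
    data = {"stance_pct": trial.stance_pct}
    for j, c in enumerate("xyz"):
        data[f"hcf_{c}"] = trial.hcf[:, j]
    for m in trial.muscles:
        f = m.force()
        for j, c in enumerate("xyz"):
            data[f"{m.name}_f{c}"] = f[:, j]
            data[f"{m.name}_a{c}"] = np.full(len(trial.stance_pct), m.attachment[j])
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def trial_from_csv(path, body_mass: float = GENERIC_BODY_MASS, profile: str = "TD") -> GaitTrial:
    df = pd.read_csv(path)
    t = df["stance_pct"].to_numpy()
    hcf = df[["hcf_x", "hcf_y", "hcf_z"]].to_numpy()
    names = sorted(
        {c[:-3] for c in df.columns if c.endswith("_fx") and c != "hcf_fx"}
    )
    muscles = []
    for name in names:
        f = df[[f"{name}_fx", f"{name}_fy", f"{name}_fz"]].to_numpy()
        mag = np.linalg.norm(f, axis=1)
        d = np.where(mag[:, None] > 1e-12, f / np.maximum(mag, 1e-12)[:, None], [1.0, 0, 0])
        att = df[[f"{name}_ax", f"{name}_ay", f"{name}_az"]].iloc[0].to_numpy()
        muscles.append(Muscle(name=name, attachment=att, direction=d, magnitude=mag))
    return GaitTrial(stance_pct=t, hcf=hcf, muscles=muscles, body_mass=body_mass, profile=profile)


def instances_to_json(instances: list, path) -> None:
    payload = [
        dict(
            instance_id=li.instance_id,
            stance_pct=li.stance_pct,
            hcf_vector=list(map(float, li.hcf_vector)),
            muscles=[
                dict(name=n, point=list(map(float, p)), force=list(map(float, f)))
                for n, p, f in li.muscle_point_loads
            ],
        )
        for li in instances
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def instances_from_json(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [
        LoadInstance(
            instance_id=e["instance_id"],
            stance_pct=e["stance_pct"],
            hcf_vector=np.asarray(e["hcf_vector"], float),
            muscle_point_loads=[
                (m["name"], np.asarray(m["point"], float), np.asarray(m["force"], float))
                for m in e["muscles"]
            ],
        )
        for e in payload
    ]
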