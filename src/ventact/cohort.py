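"""Virtual-subject cohort: ground truths and (noisy) target data.

A virtual subject pairs a synthetic biventricular mesh with a ground-truth
parameter set and the simulated target data (epicardial activation map and
12-lead QRS), in clean and 20 dB white-Gaussian-noise-contaminated
variants.  The default cohort crosses the four anatomy presets with the
five conduction-speed configurations (20 subjects).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from ventact.geometry import (
    ANATOMY_PRESETS,
    BiventricularMesh,
    CandidateRootNodes,
    ElectrodeSet,
    assign_fibre_frames,
    discretise_root_candidates,
    generate_synthetic_mesh,
    place_electrodes,
)
from ventact.eikonal import (
    ActivationMap,
    ConductionSpeeds,
    ParameterSet,
    build_propagation_graph,
    extract_epicardial_map,
    simulate_activation,
)
from ventact.pseudo_ecg import PseudoECGModel, QRSRecording, compute_qrs


class CohortError(ValueError):
    pass


#: the five named conduction-speed configurations
#: (endocardial / fibre / sheet / sheet-normal, cm/s)
SPEED_PRESETS = {
    "Normal speeds": (150.0, 50.0, 32.0, 29.0),
    "Slow endocardial speed": (120.0, 50.0, 32.0, 29.0),
    "Fast endocardial speed": (179.0, 50.0, 32.0, 29.0),
    "Fast endocardial and myocardial speeds": (179.0, 88.0, 49.0, 45.0),
    "Slow endocardial and fast myocardial speeds": (120.0, 88.0, 49.0, 45.0),
}


def speed_configurations() -> dict:
    """The five named ConductionSpeeds presets."""
    return {name: ConductionSpeeds(*vals) for name, vals in SPEED_PRESETS.items()}


def add_white_noise(signal: np.ndarray, snr_db: float = 20.0, seed: int = 0) -> np.ndarray:
    """Additive white Gaussian noise at the requested SNR.

    Noise variance = signal power / 10^(snr_db / 10), with signal power the
    mean square over the full support of the input.  Deterministic given
    ``seed``.
    """
    x = np.asarray(signal, dtype=float)
    power = float(np.mean(x**2))
    if power == 0.0:
        raise CohortError("zero-power signal cannot be noise-contaminated")
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    return x + rng.normal(0.0, sigma, size=x.shape)


def measured_snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Empirical SNR estimate in dB over the signal support."""
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noisy, dtype=float) - clean
    return 10.0 * np.log10(np.mean(clean**2) / np.mean(noise**2))


@dataclass
class VirtualSubject:
    """Ground truth plus clean/noisy target data for one synthetic subject."""

    mesh: BiventricularMesh
    candidates: CandidateRootNodes
    electrodes: ElectrodeSet
    truth: ParameterSet
    atm_clean: ActivationMap        # epicardial restriction
    atm_noisy: ActivationMap
    qrs_clean: QRSRecording
    qrs_noisy: QRSRecording
    seed: int
    speed_preset: str | None = None

    def target(self, modality: str, noisy: bool = True):
        modality = modality.upper()
        if modality == "ATM":
            return self.atm_noisy if noisy else self.atm_clean
        if modality == "ECG":
            return self.qrs_noisy if noisy else self.qrs_clean
        raise CohortError(f"unknown modality {modality!r}")


def make_virtual_subject(
    mesh: BiventricularMesh,
    candidates: CandidateRootNodes,
    speeds: ConductionSpeeds,
    n_roots: int = 7,
    seed: int = 0,
    snr_db: float = 20.0,
    speed_preset: str | None = None,
    electrodes: ElectrodeSet | None = None,
) -> VirtualSubject:
    """Build one virtual subject with simulated clean and noisy targets.

    Ground-truth root nodes are ``n_roots`` candidates drawn uniformly
    without replacement (seeded).  The noisy targets receive independent
    white Gaussian noise at ``snr_db``.
    """
    if not (6 <= n_roots <= 10):
        raise CohortError(f"n_roots {n_roots} outside [6, 10]")
    if candidates.n_candidates < n_roots:
        raise CohortError("not enough candidate root nodes")
    ss = np.random.SeedSequence(seed)
    root_seed, atm_noise_seed, qrs_noise_seed = ss.spawn(3)

    rng = np.random.default_rng(root_seed)
    chosen = rng.choice(candidates.n_candidates, size=n_roots, replace=False)
    active = np.zeros(candidates.n_candidates, dtype=bool)
    active[chosen] = True
    truth = ParameterSet(speeds=speeds, root_active=active)
    truth.validate()

    if electrodes is None:
        electrodes = place_electrodes(mesh)
    graph = build_propagation_graph(mesh)
    atm_full = simulate_activation(mesh, candidates, truth, graph=graph)
    atm_clean = extract_epicardial_map(atm_full, mesh)
    qrs_clean = compute_qrs(atm_full, mesh, electrodes)

    atm_noise_rng_seed = int(np.random.default_rng(atm_noise_seed).integers(2**31))
    qrs_noise_rng_seed = int(np.random.default_rng(qrs_noise_seed).integers(2**31))
    atm_noisy = ActivationMap(
        times_ms=add_white_noise(atm_clean.times_ms, snr_db, atm_noise_rng_seed),
        node_ids=atm_clean.node_ids.copy(),
    )
    qrs_noisy = QRSRecording(
        time_ms=qrs_clean.time_ms.copy(),
        samples=add_white_noise(qrs_clean.samples, snr_db, qrs_noise_rng_seed),
    )
    return VirtualSubject(
        mesh=mesh, candidates=candidates, electrodes=electrodes, truth=truth,
        atm_clean=atm_clean, atm_noisy=atm_noisy,
        qrs_clean=qrs_clean, qrs_noisy=qrs_noisy,
        seed=seed, speed_preset=speed_preset,
    )


def build_cohort(
    edge_length: float = 0.42,
    resolution: str = "LOW",
    n_roots: int = 7,
    base_seed: int = 0,
    anatomies: dict | None = None,
) -> list:
    """The default cohort: 4 anatomy presets x 5 speed presets = 20 subjects.

    Subject seeds derive deterministically from ``base_seed`` so the whole
    cohort regenerates bit-identically from a manifest.
    """
    anatomies = anatomies or ANATOMY_PRESETS
    subjects = []
    idx = 0
    for anat_name, anat in anatomies.items():
        mesh = assign_fibre_frames(generate_synthetic_mesh(
            axes=anat["axes"], wall_thickness=anat["wall_thickness"],
            edge_length=edge_length, seed=base_seed + idx,
        ))
        candidates = discretise_root_candidates(mesh, resolution)
        electrodes = place_electrodes(mesh)
        for preset_name, speeds in speed_configurations().items():
            subj = make_virtual_subject(
                mesh, candidates, speeds, n_roots=n_roots,
                seed=base_seed * 10000 + idx, speed_preset=preset_name,
                electrodes=electrodes,
            )
            subj.speed_preset = preset_name
            subjects.append((anat_name, preset_name, subj))
            idx += 1
    return subjects


def noise_scale_tolerance(
    clean_target, modality: str, n_realisations: int = 10, snr_db: float = 20.0,
    seed: int = 0, dtw_cfg=None,
) -> float:
    """Default ABC tolerance: mean discrepancy between the clean target and
    independent noise realisations of itself."""
    from ventact.discrepancy import atm_rmse, ecg_discrepancy

    modality = modality.upper()
    vals = []
    for i in range(n_realisations):
        if modality == "ATM":
            noisy = ActivationMap(
                times_ms=add_white_noise(clean_target.times_ms, snr_db, seed + i),
                node_ids=clean_target.node_ids,
            )
            vals.append(float(atm_rmse(noisy, clean_target)))
        elif modality == "ECG":
            noisy = QRSRecording(
                time_ms=clean_target.time_ms,
                samples=add_white_noise(clean_target.samples, snr_db, seed + i),
            )
            vals.append(float(ecg_discrepancy(noisy, clean_target, dtw_cfg)))
        else:
            raise CohortError(f"unknown modality {modality!r}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# subject bundle I/O


def save_subject(subject: VirtualSubject, directory) -> None:
    from ventact.geometry import save_candidates_csv, save_electrodes_csv, save_mesh_vtk
    from ventact.eikonal import save_activation_csv
    from ventact.pseudo_ecg import save_qrs_csv

    os.makedirs(directory, exist_ok=True)
    save_mesh_vtk(subject.mesh, os.path.join(directory, "mesh.vtk"))
    save_candidates_csv(subject.candidates, os.path.join(directory, "candidates.csv"))
    save_electrodes_csv(subject.electrodes, os.path.join(directory, "electrodes.csv"))
    save_activation_csv(subject.atm_clean, os.path.join(directory, "atm_clean.csv"))
    save_activation_csv(subject.atm_noisy, os.path.join(directory, "atm_noisy.csv"))
    save_qrs_csv(subject.qrs_clean, os.path.join(directory, "qrs_clean.csv"))
    save_qrs_csv(subject.qrs_noisy, os.path.join(directory, "qrs_noisy.csv"))
    truth = {
        "speeds": list(subject.truth.speeds.as_array()),
        "root_active": [int(b) for b in subject.truth.root_active],
    }
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    manifest = {
        "seed": subject.seed,
        "speed_preset": subject.speed_preset,
        "resolution": subject.candidates.resolution,
        "mesh_metadata": {
            k: v for k, v in subject.mesh.metadata.items()
        },
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
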