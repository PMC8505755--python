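"""Pseudo-ECG forward model: 12-lead QRS complexes from activation maps.

The extracellular potential at an electrode is the volume sum of
per-element transmembrane-potential gradients dotted with the gradient of
1/r to the electrode (homogeneous infinite-volume conductor).  The
transmembrane potential surrogate is a unit tanh upstroke centred at each
node's activation time.  Sampling interval is 1 ms (1 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ventact.geometry import BiventricularMesh, ElectrodeSet
from ventact.eikonal import ActivationMap

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")

#: the 8 linearly independent leads used for discrepancy computation
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

MEASUREMENT_ELECTRODES = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")


class PseudoECGError(RuntimeError):
    pass


@dataclass
class QRSRecording:
    """Standardised 12-lead QRS complex at 1 ms resolution.

    ``samples`` has one column per lead in ``LEAD_NAMES`` order; amplitudes
    are dimensionless after joint (all-lead) standardisation.
    """

    time_ms: np.ndarray       # (T,)
    samples: np.ndarray       # (T, 12)
    lead_names: tuple = LEAD_NAMES

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_ms(self) -> float:
        """QRS width in ms (span of the trimmed support)."""
        return float(self.time_ms[-1] - self.time_ms[0])

    def lead(self, name: str) -> np.ndarray:
        return self.samples[:, self.lead_names.index(name)]


def vm_waveform(t, activation_time, upstroke_tau: float = 1.0):
    """Transmembrane-potential surrogate: smooth unit step at activation.

    vm(t) = 0.5 * (1 + tanh((t - AT) / tau)); monotone in t, in (0, 1),
    with vm(AT) = 0.5 and vm(AT + x) + vm(AT - x) = 1.
    """
    if upstroke_tau <= 0:
        raise PseudoECGError("upstroke_tau must be positive")
    t = np.asarray(t, dtype=float)
    at = np.asarray(activation_time, dtype=float)
    return 0.5 * (1.0 + np.tanh((t - at) / upstroke_tau))


def _element_gradient_operator(mesh: BiventricularMesh) -> np.ndarray:
    """Per-element (M, 3, 4) matrices mapping nodal values to the linear
    gradient inside each tetrahedron."""
    p = mesh.nodes[mesh.elements]
    edges = p[:, 1:] - p[:, :1]                     # (M, 3, 3): rows = edges
    inv = np.linalg.inv(edges)                      # solves edges @ g = dv
    op = np.zeros((mesh.n_elements, 3, 4))
    op[:, :, 1:] = inv
    op[:, :, 0] = -inv.sum(axis=2)
    return op


def _lead_field_vectors(mesh: BiventricularMesh, electrode_position: np.ndarray) -> np.ndarray:
    """Per-element Vol * grad(1/r) evaluated at element centroids, (M, 3)."""
    centroids = mesh.element_centroids()
    d = centroids - np.asarray(electrode_position, dtype=float)
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise PseudoECGError("electrode lies inside (or on) a mesh element")
    vols = mesh.element_volumes()
    return -(d / r[:, None] ** 3) * vols[:, None]


def electrode_potential(
    atm: ActivationMap,
    mesh: BiventricularMesh,
    electrode_position: np.ndarray,
    t,
    upstroke_tau: float = 1.0,
    amplitude_constant: float = 1.0,
) -> np.ndarray:
    """Pseudo-ECG potential(s) at one electrode for time(s) ``t`` (ms).

    phi(t) = -K * sum_elements [grad vm(t)]_e . grad(1/r)_e . Vol_e.
    A spatially uniform vm yields phi = 0 identically.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    grad_op = _element_gradient_operator(mesh)
    lead = _lead_field_vectors(mesh, electrode_position)
    at = atm.times_ms
    vm = vm_waveform(t[:, None], at[None, :], upstroke_tau)  # (T, N)
    vm_elem = vm[:, mesh.elements]                           # (T, M, 4)
    grad_vm = np.einsum("mij,tmj->tmi", grad_op, vm_elem)    # (T, M, 3)
    return -amplitude_constant * np.einsum("tmi,mi->t", grad_vm, lead)


class PseudoECGModel:
    """Precomputed pseudo-ECG operator for one mesh + electrode set.

    Collapses the per-element gradient and lead-field contractions into one
    (n_electrodes, N) transfer matrix so that potentials are a single
    matmul per activation map.
    """

    def __init__(self, mesh: BiventricularMesh, electrodes: ElectrodeSet,
                 upstroke_tau: float = 1.0, amplitude_constant: float = 1.0):
        self.mesh = mesh
        self.electrodes = electrodes
        self.tau = float(upstroke_tau)
        self.k = float(amplitude_constant)
        grad_op = _element_gradient_operator(mesh)
        n = mesh.n_nodes
        self._transfer = np.zeros((len(MEASUREMENT_ELECTRODES), n))
        for row, name in enumerate(MEASUREMENT_ELECTRODES):
            lead = _lead_field_vectors(mesh, electrodes.position(name))
            coef = np.einsum("mij,mi->mj", grad_op, lead)     # (M, 4)
            np.add.at(self._transfer[row], self.mesh.elements.ravel(), -self.k * coef.ravel())

    def potentials(self, atm: ActivationMap, time_ms: np.ndarray) -> np.ndarray:
        """(T, n_electrodes) potentials over the given time grid."""
        vm = vm_waveform(time_ms[:, None], atm.times_ms[None, :], self.tau)
        return vm @ self._transfer.T


def _derive_leads(pot: np.ndarray) -> np.ndarray:
    """12 standard leads from the 9 measurement-electrode potentials."""
    cols = {name: pot[:, i] for i, name in enumerate(MEASUREMENT_ELECTRODES)}
    ra, la, ll = cols["RA"], cols["LA"], cols["LL"]
    wct = (ra + la + ll) / 3.0
    leads = {
        "I": la - ra,
        "II": ll - ra,
        "III": ll - la,
        "aVR": ra - (la + ll) / 2.0,
        "aVL": la - (ra + ll) / 2.0,
        "aVF": ll - (ra + la) / 2.0,
    }
    for i in range(1, 7):
        leads[f"V{i}"] = cols[f"V{i}"] - wct
    return np.column_stack([leads[nm] for nm in LEAD_NAMES])


def compute_qrs(
    atm: ActivationMap,
    mesh: BiventricularMesh,
    electrodes: ElectrodeSet,
    sampling_ms: float = 1.0,
    upstroke_tau: float = 1.0,
    model: PseudoECGModel | None = None,
    support_fraction: float = 0.01,
) -> QRSRecording:
    """Compute the standardised 12-lead QRS for an activation map.

    Potentials are simulated on a 1 ms grid spanning the activation map plus
    5 tau of padding, leads are derived (Einthoven, Goldberger, Wilson),
    jointly standardised by the maximum absolute amplitude over all 12
    leads, and trimmed to the support where any lead exceeds
    ``support_fraction`` of the peak.
    """
    if model is None:
        model = PseudoECGModel(mesh, electrodes, upstroke_tau=upstroke_tau)
    if np.ptp(atm.times_ms) == 0.0:
        raise PseudoECGError("degenerate activation: spatially uniform activation times")
    pad = 5.0 * model.tau
    t0 = np.floor(atm.times_ms.min() - pad)
    t1 = np.ceil(atm.times_ms.max() + pad)
    time_ms = np.arange(t0, t1 + sampling_ms / 2, sampling_ms)
    pot = model.potentials(atm, time_ms)
    leads = _derive_leads(pot)
    peak = np.abs(leads).max()
    if peak == 0.0:
        raise PseudoECGError("degenerate activation: all electrode potentials are zero")
    leads = leads / peak
    active = np.flatnonzero(np.abs(leads).max(axis=1) > support_fraction)
    leads = leads[active[0] : active[-1] + 1]
    time_ms = time_ms[active[0] : active[-1] + 1]
    return QRSRecording(time_ms=time_ms - time_ms[0], samples=leads)


def save_qrs_csv(qrs: QRSRecording, path) -> None:
    header = "time_ms," + ",".join(qrs.lead_names)
    data = np.column_stack([qrs.time_ms, qrs.samples])
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")


def load_qrs_csv(path) -> QRSRecording:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    return QRSRecording(time_ms=data[:, 0], samples=data[:, 1:13])
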