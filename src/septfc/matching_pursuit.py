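"""Gabor-dictionary matching pursuit for evoked-potential decomposition.

An averaged SEP trace is approximated greedily as a sum of Gabor atoms

    g(t) = K * exp(-pi * ((t - u) / s)**2) * cos(2*pi*f*(t - u) + phi)

with center time ``u``, scale ``s``, modulation frequency ``f`` and phase
``phi``; ``K`` normalizes the discretized waveform to unit L2 norm. At every
pursuit step the dictionary atom with the largest energy projection onto the
current residual is selected and its projection subtracted. The phase is not
enumerated: for each (u, s, f) the residual is projected onto the
two-dimensional span of the cosine- and sine-modulated windows, which yields
the optimal phase in closed form.

Each extracted atom is summarized as a time-frequency component (TFC) with
latency (ms), frequency (Hz), power (µV², the squared projection amplitude)
and relative energy (power as a fraction of the input signal energy). The
sequence of TFCs, ordered by extraction, is the feature substrate for all
downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .recording import SEPRecording, ValidationError

__all__ = [
    "DictionaryConfig",
    "GaborAtom",
    "TFC",
    "GaborDictionary",
    "build_dictionary",
    "gabor_waveform",
    "mp_decompose",
    "reconstruct",
    "time_frequency_map",
    "tfc_table",
]

# atoms are numerically zero beyond this many scales from the center
_SUPPORT_SIGMAS = 6.0


@dataclass(frozen=True)
class DictionaryConfig:
    """Granularity of the Gabor dictionary.

    ``scale_min_samples``: smallest dyadic scale (samples).
    ``translation_step_factor``: center-time grid step as a fraction of the
    scale (0.5 -> step s/2).
    ``frequency_step_factor``: frequency grid step as a fraction of
    ``sampling_rate / s`` (0.5 -> step rate / (2 s)).
    """

    scale_min_samples: int = 2
    translation_step_factor: float = 0.5
    frequency_step_factor: float = 0.5


DEFAULT_DICTIONARY = DictionaryConfig()


@dataclass(frozen=True)
class GaborAtom:
    """One unit-norm Gabor atom with its projection amplitude.

    ``coefficient`` is the (nonnegative) amplitude of the projection of the
    residual onto the unit-norm atom waveform, in µV; the sign is absorbed
    into the phase.
    """

    center_time_ms: float
    scale_ms: float
    frequency_hz: float
    phase: float
    coefficient: float


@dataclass(frozen=True)
class TFC:
    """Derived time-frequency component parameters of one atom."""

    time_ms: float
    frequency_hz: float
    power: float  # µV², = coefficient**2
    relative_energy: float  # fraction of input signal energy
    rank: int  # extraction order, 1 = largest


def _dyadic_scales(n_samples: int, config: DictionaryConfig) -> list[int]:
    max_j = int(np.floor(np.log2(n_samples))) - 1
    scales = [2**j for j in range(1, max_j + 1)]
    return [s for s in scales if s >= config.scale_min_samples]


def gabor_waveform(
    n_samples: int,
    sampling_rate: float,
    center_time_ms: float,
    scale_ms: float,
    frequency_hz: float,
    phase: float = 0.0,
) -> np.ndarray:
    """Materialize a unit-L2-norm Gabor atom on the sample grid."""
    t_ms = np.arange(n_samples) / sampling_rate * 1e3
    env = np.exp(-np.pi * ((t_ms - center_time_ms) / scale_ms) ** 2)
    wave = env * np.cos(2 * np.pi * frequency_hz * (t_ms - center_time_ms) / 1e3 + phase)
    norm = np.linalg.norm(wave)
    if norm == 0:
        raise ValidationError("degenerate atom: zero norm on this sample grid")
    return wave / norm


class GaborDictionary:
    """Deterministic (u, s, f) grid with precomputed orthonormal atom pairs.

    For every grid triple the cosine- and sine-modulated windows are
    orthonormalized into (e1, e2); projecting a residual onto that pair gives
    the energy captured by the best-phase atom in closed form. Atoms are
    stored sorted by (u, f, s) so that ``argmax`` over projection energies
    breaks ties toward smallest u, then f, then s.
    """

    def __init__(self, n_samples: int, sampling_rate: float, config: DictionaryConfig):
        if n_samples < 16:
            raise ValidationError("dictionary requires n_samples >= 16")
        self.n_samples = int(n_samples)
        self.sampling_rate = float(sampling_rate)
        self.config = config

        scales = _dyadic_scales(n_samples, config)
        if not scales:
            raise ValidationError("dictionary grid is empty for this configuration")

        t = np.arange(n_samples, dtype=float)
        us, ss, fs = [], [], []
        for s in scales:
            step_u = max(1, int(round(s * config.translation_step_factor)))
            u_grid = np.arange(0, n_samples, step_u, dtype=float)
            f_step = sampling_rate * config.frequency_step_factor / s
            f_grid = np.arange(0.0, sampling_rate / 2.0, f_step)
            uu, ff = np.meshgrid(u_grid, f_grid, indexing="ij")
            us.append(uu.ravel())
            ss.append(np.full(uu.size, float(s)))
            fs.append(ff.ravel())
        u = np.concatenate(us)
        s_arr = np.concatenate(ss)
        f = np.concatenate(fs)
        order = np.lexsort((s_arr, f, u))  # primary u, then f, then s
        self.u_samples = u[order]
        self.s_samples = s_arr[order]
        self.f_hz = f[order]
        self.n_atoms = self.u_samples.size

        e1 = np.empty((self.n_atoms, n_samples))
        e2 = np.zeros((self.n_atoms, n_samples))
        # build per scale in bulk; loop over frequencies within a scale
        for s in scales:
            idx = np.flatnonzero(self.s_samples == s)
            u_unique = np.unique(self.u_samples[idx])
            offsets = t[None, :] - u_unique[:, None]
            env = np.exp(-np.pi * (offsets / s) ** 2)
            env[np.abs(offsets) > _SUPPORT_SIGMAS * s] = 0.0
            for fval in np.unique(self.f_hz[idx]):
                jdx = idx[self.f_hz[idx] == fval]
                u_j = self.u_samples[jdx]
                theta = 2 * np.pi * fval / sampling_rate * (t[None, :] - u_j[:, None])
                env_j = env[np.searchsorted(u_unique, u_j)]
                gc = env_j * np.cos(theta)
                gs = env_j * np.sin(theta)
                nc = np.linalg.norm(gc, axis=1)
                b1 = gc / nc[:, None]
                x = np.einsum("ij,ij->i", gs, b1)
                r2 = gs - x[:, None] * b1
                n2 = np.linalg.norm(r2, axis=1)
                ok = n2 > 1e-10
                b2 = np.zeros_like(r2)
                b2[ok] = r2[ok] / n2[ok, None]
                e1[jdx] = b1
                e2[jdx] = b2
        self.e1 = e1
        self.e2 = e2
        # single-precision copies for the selection scan (the chosen atom's
        # projection is recomputed in double precision before subtraction)
        self._e1f = e1.astype(np.float32)
        self._e2f = e2.astype(np.float32)

    # -- queries -----------------------------------------------------------

    def atom_waveform(self, index: int, phase: float) -> np.ndarray:
        return gabor_waveform(
            self.n_samples,
            self.sampling_rate,
            self.u_samples[index] / self.sampling_rate * 1e3,
            self.s_samples[index] / self.sampling_rate * 1e3,
            self.f_hz[index],
            phase,
        )

    def projection_energies(self, residual: np.ndarray) -> np.ndarray:
        """Energy captured by the best-phase atom at every grid triple."""
        a1 = self.e1 @ residual
        a2 = self.e2 @ residual
        return a1 * a1 + a2 * a2

    def _selection_energies(self, residual: np.ndarray) -> np.ndarray:
        """Single-precision projection energies for the greedy scan."""
        r32 = residual.astype(np.float32)
        a1 = self._e1f @ r32
        a2 = self._e2f @ r32
        return (a1 * a1 + a2 * a2).astype(float)

    def expected_size(self) -> int:
        """Closed-form grid size implied by the step rules (for validation)."""
        total = 0
        for s in _dyadic_scales(self.n_samples, self.config):
            step_u = max(1, int(round(s * self.config.translation_step_factor)))
            n_u = int(np.ceil(self.n_samples / step_u))
            f_step = self.sampling_rate * self.config.frequency_step_factor / s
            n_f = int(np.ceil((self.sampling_rate / 2.0) / f_step))
            total += n_u * n_f
        return total


@lru_cache(maxsize=8)
def _cached_dictionary(n_samples: int, sampling_rate: float, config: DictionaryConfig):
    return GaborDictionary(n_samples, sampling_rate, config)


def build_dictionary(
    n_samples: int,
    sampling_rate: float,
    config: DictionaryConfig | None = None,
) -> GaborDictionary:
    """Build (or fetch from cache) the Gabor dictionary for a sample grid."""
    return _cached_dictionary(int(n_samples), float(sampling_rate), config or DEFAULT_DICTIONARY)


def _projection(
    residual: np.ndarray, t: np.ndarray, fs: float, u: float, s: float, f: float
):
    """Project a residual onto the best-phase atom at continuous (u, s, f).

    Returns ``(energy, w, phi)`` where ``w`` is the projection waveform onto
    the two-dimensional cos/sin atom span and ``phi`` the optimal phase.
    """
    env = np.exp(-np.pi * ((t - u) / s) ** 2)
    theta = 2 * np.pi * f / fs * (t - u)
    gc = env * np.cos(theta)
    gs = env * np.sin(theta)
    g11 = gc @ gc
    g12 = gc @ gs
    g22 = gs @ gs
    r1 = gc @ residual
    r2 = gs @ residual
    det = g11 * g22 - g12 * g12
    if g11 <= 0:
        return 0.0, np.zeros_like(residual), 0.0
    if g22 < 1e-12 * g11 or det < 1e-14 * g11 * max(g22, 1e-30):
        p, q = r1 / g11, 0.0
    else:
        p = (g22 * r1 - g12 * r2) / det
        q = (g11 * r2 - g12 * r1) / det
    w = p * gc + q * gs
    energy = float(p * r1 + q * r2)  # = ||proj||^2
    phi = float(np.mod(np.arctan2(-q, p), 2 * np.pi))
    return max(energy, 0.0), w, phi


def _refine_params(
    residual: np.ndarray,
    t: np.ndarray,
    fs: float,
    u0: float,
    s0: float,
    f0: float,
    n_samples: int,
) -> tuple[float, float, float]:
    """Continuously refine (u, s, f) around a selected grid triple.

    The dyadic grid localizes components only to within half a translation /
    frequency step, which is far coarser than the latency and frequency
    effects of interest; a bounded Nelder-Mead polish within one grid cell
    restores continuous-parameter resolution (high-resolution pursuit).
    """
    from scipy.optimize import minimize

    du = s0 / 2.0
    df = fs / (2.0 * s0)

    def objective(p):
        u, ls, f = p
        energy, _, _ = _projection(residual, t, fs, u, np.exp(ls), f)
        return -energy

    bounds = [
        (max(0.0, u0 - du), min(float(n_samples - 1), u0 + du)),
        (np.log(s0 / np.sqrt(2)), np.log(s0 * np.sqrt(2))),
        (max(0.0, f0 - df), min(fs / 2.0, f0 + df)),
    ]
    res = minimize(
        objective,
        x0=np.array([u0, np.log(s0), f0]),
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxiter": 150, "xatol": 5e-4, "fatol": 1e-12},
    )
    u, ls, f = res.x
    return float(u), float(np.exp(ls)), float(f)


def _atom_from_projection(
    dictionary: GaborDictionary, index: int, residual: np.ndarray, refine: bool
) -> tuple[GaborAtom, np.ndarray]:
    """Best-phase (optionally refined) atom at a selected grid triple."""
    fs = dictionary.sampling_rate
    u = float(dictionary.u_samples[index])
    s = float(dictionary.s_samples[index])
    f = float(dictionary.f_hz[index])
    t = np.arange(dictionary.n_samples, dtype=float)
    if refine:
        grid_energy, _, _ = _projection(residual, t, fs, u, s, f)
        u_r, s_r, f_r = _refine_params(residual, t, fs, u, s, f, dictionary.n_samples)
        energy, w, phi = _projection(residual, t, fs, u_r, s_r, f_r)
        if energy >= grid_energy:
            u, s, f = u_r, s_r, f_r
        else:  # polish failed to improve; keep the grid atom
            energy, w, phi = _projection(residual, t, fs, u, s, f)
    else:
        energy, w, phi = _projection(residual, t, fs, u, s, f)
    atom = GaborAtom(
        center_time_ms=u / fs * 1e3,
        scale_ms=s / fs * 1e3,
        frequency_hz=f,
        phase=phi,
        coefficient=float(np.sqrt(energy)),
    )
    return atom, w


def mp_decompose(
    recording: SEPRecording,
    max_atoms: int = 50,
    residual_energy_stop: float = 0.002,
    config: DictionaryConfig | None = None,
    refine: bool = True,
) -> list[tuple[GaborAtom, TFC]]:
    """Greedy matching pursuit of a recording against the Gabor dictionary.

    Iterates until the residual energy falls to ``residual_energy_stop`` of
    the signal energy or ``max_atoms`` have been extracted, whichever comes
    first. Each step subtracts the orthogonal projection onto the selected
    best-phase atom, so signal energy is conserved exactly between the
    extracted powers and the residual. Atoms come back in extraction order
    (rank 1 = largest); an all-zero signal yields an empty list.
    """
    if max_atoms < 1:
        raise ValidationError("max_atoms must be >= 1")
    if not (0 <= residual_energy_stop < 1):
        raise ValidationError("residual_energy_stop must be in [0, 1)")
    x = np.asarray(recording.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    signal_energy = float(x @ x)
    if signal_energy == 0.0:
        return []

    dictionary = build_dictionary(recording.n_samples, recording.sampling_rate, config)
    t_shift = recording.t0_offset_ms
    residual = x.copy()
    out: list[tuple[GaborAtom, TFC]] = []
    for rank in range(1, max_atoms + 1):
        gains = dictionary._selection_energies(residual)
        index = int(np.argmax(gains))  # ties -> first = smallest (u, f, s)
        if gains[index] <= 0.0:
            break
        atom, w = _atom_from_projection(dictionary, index, residual, refine)
        residual -= w
        if t_shift != 0.0:
            atom = GaborAtom(
                center_time_ms=atom.center_time_ms + t_shift,
                scale_ms=atom.scale_ms,
                frequency_hz=atom.frequency_hz,
                phase=atom.phase,
                coefficient=atom.coefficient,
            )
        power = atom.coefficient**2
        out.append(
            (atom, TFC(atom.center_time_ms, atom.frequency_hz, power, power / signal_energy, rank))
        )
        if float(residual @ residual) / signal_energy <= residual_energy_stop:
            break
    return out


def reconstruct(
    atoms, n_samples: int, sampling_rate: float, t0_offset_ms: float = 0.0
) -> np.ndarray:
    """Sum of coefficient-weighted atom waveforms on a sample grid."""
    out = np.zeros(int(n_samples))
    for atom in atoms:
        out += atom.coefficient * gabor_waveform(
            n_samples,
            sampling_rate,
            atom.center_time_ms - t0_offset_ms,
            atom.scale_ms,
            atom.frequency_hz,
            atom.phase,
        )
    return out


def time_frequency_map(atoms, time_grid_ms: np.ndarray, freq_grid_hz: np.ndarray) -> np.ndarray:
    """Wigner-style energy density of a set of atoms (cross terms discarded).

    Each atom contributes a bivariate Gaussian blob centered at (u, f) with
    time SD ``s / (2 sqrt(pi))`` ms and frequency SD ``1000 / (2 sqrt(pi) s)``
    Hz, scaled so its integral equals the atom's power. The Riemann sum of the
    returned map therefore approximates the total extracted power, up to grid
    truncation.
    """
    time_grid_ms = np.asarray(time_grid_ms, dtype=float)
    freq_grid_hz = np.asarray(freq_grid_hz, dtype=float)
    if time_grid_ms.size == 0 or freq_grid_hz.size == 0:
        raise ValidationError("time and frequency grids must be non-empty")
    tt = time_grid_ms[:, None]
    ff = freq_grid_hz[None, :]
    out = np.zeros((time_grid_ms.size, freq_grid_hz.size))
    for atom in atoms:
        sigma_t = atom.scale_ms / (2 * np.sqrt(np.pi))
        sigma_f = 1e3 / (2 * np.sqrt(np.pi) * atom.scale_ms)
        amp = atom.coefficient**2 / (2 * np.pi * sigma_t * sigma_f)
        out += amp * np.exp(
            -((tt - atom.center_time_ms) ** 2) / (2 * sigma_t**2)
            - ((ff - atom.frequency_hz) ** 2) / (2 * sigma_f**2)
        )
    return out


def tfc_table(decompositions: dict) -> "pandas.DataFrame":  # noqa: F821
    """Flatten ``{(subject_id, condition): [(atom, tfc), ...]}`` to a table.

    Columns: subject_id, condition, rank, time_ms, frequency_hz, power_uv2,
    relative_energy.
    """
    import pandas as pd

    rows = []
    for (subject_id, condition), pairs in decompositions.items():
        for _, tfc in pairs:
            rows.append(
                {
                    "subject_id": subject_id,
                    "condition": str(getattr(condition, "value", condition)),
                    "rank": tfc.rank,
                    "time_ms": tfc.time_ms,
                    "frequency_hz": tfc.frequency_hz,
                    "power_uv2": tfc.power,
                    "relative_energy": tfc.relative_energy,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "rank",
            "time_ms",
            "frequency_hz",
            "power_uv2",
            "relative_energy",
        ],
    )
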