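"""Staged IR ion-spectrum simulation, broadening, matching and assignment.

The workflow mirrors how gas-phase ion structures are assigned by
infrared ion spectroscopy:

1. conformer search -- distance-geometry embedding of the SMILES-defined
   cation (default 500 random conformers) minimized with a classical
   forcefield;
2. diversity selection -- greedy max-min heavy-atom RMSD pruning to at
   most 40 conformers;
3. energy window -- screening-energy filter at 40 kJ/mol (80 kJ/mol for
   pyranosyl cations, whose landscapes are broader);
4. harmonic frequencies scaled by 0.975, stick spectra broadened with a
   20 cm^-1 (FWHM) unit-area Gaussian on a 1 cm^-1 grid over the
   700-1850 cm^-1 instrument range;
5. Boltzmann-weighted ensemble trace (298 K), cosine-similarity matching
   against an experimental trace, and diagnostic-band classification of
   the ion type (oxocarbenium / dioxolenium / ring-opened).

Diagnostic windows follow the established band assignments: the
C1=O5+ oxocarbenium stretch near 1600 cm^-1 with a preserved acetyl C=O
near 1800 cm^-1; dioxolenium O-C=O+ stretch near 1550 cm^-1 with its
bend near 1500 cm^-1; ring-opened species pair the dioxolenium stretch
with a regenerated carbonyl at 1730-1790 cm^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .records import ConformerRecord
from . import thermo

__all__ = [
    "Spectrum",
    "PipelineConfig",
    "IonAssignment",
    "conformer_search",
    "diversity_select",
    "filter_by_energy",
    "scale_frequencies",
    "broaden",
    "ensemble_spectrum",
    "match_score",
    "classify_ion_type",
    "run_pipeline",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
    "DEFAULT_BAND_TABLE",
]

WORKING_RANGE = (700.0, 1850.0)  # cm^-1, instrument frequency range


@dataclass(frozen=True)
class Spectrum:
    """A vibrational line list or a continuous trace.

    ``positions`` in cm^-1 (strictly increasing for traces),
    ``intensities`` non-negative, arbitrary units.
    """

    positions: np.ndarray
    intensities: np.ndarray
    kind: str = "line-list"  # "line-list" | "trace"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.shape != inten.shape or pos.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1D")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        if self.kind == "trace" and pos.size > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("trace positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    @property
    def range(self) -> tuple[float, float]:
        return (float(self.positions.min()), float(self.positions.max()))

    def resample(self, grid: np.ndarray) -> "Spectrum":
        if self.kind != "trace":
            raise ValueError("only traces can be resampled")
        return Spectrum(grid, np.interp(grid, self.positions, self.intensities, left=0.0, right=0.0), "trace")


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters of the simulation workflow (see module docstring)."""

    n_conformers: int = 500
    max_selected: int = 40
    energy_cutoff: float = 40.0  # kJ/mol
    pyranosyl_cutoff: float = 80.0  # kJ/mol
    scale_factor: float = 0.975
    broaden_width: float = 20.0  # cm^-1, FWHM by default
    width_is_fwhm: bool = True
    temperature: float = thermo.IR_TEMPERATURE  # K
    seed: int = 2024
    grid_spacing: float = 1.0  # cm^-1
    working_range: tuple[float, float] = WORKING_RANGE

    def __post_init__(self):
        if min(self.n_conformers, self.max_selected) <= 0:
            raise ValueError("counts must be positive")
        if min(self.energy_cutoff, self.pyranosyl_cutoff, self.broaden_width,
               self.temperature, self.grid_spacing) <= 0:
            raise ValueError("cutoffs, width, temperature, spacing must be positive")
        if not (0.0 < self.scale_factor <= 1.2):
            raise ValueError("scale_factor must lie in (0, 1.2]")

    def grid(self) -> np.ndarray:
        lo, hi = self.working_range
        return np.arange(lo, hi + self.grid_spacing / 2.0, self.grid_spacing)


@dataclass(frozen=True)
class IonAssignment:
    """Structural call for a glycosyl-cation IR trace, with band evidence."""

    label: str  # oxocarbenium | dioxolenium | ring-opened | mixed/indeterminate
    evidence: dict  # band name -> {"present": bool, "position": float | None}

    def to_json(self) -> str:
        return json.dumps({"label": self.label, "evidence": self.evidence},
                          sort_keys=True, indent=2)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def conformer_search(smiles: str, config: PipelineConfig | None = None,
                     backend=None) -> list[ConformerRecord]:
    """Distance-geometry conformer generation, forcefield-minimized.

    Embeds ``config.n_conformers`` random 3D conformations of the
    SMILES-defined cation (seeded, reproducible) and minimizes each with
    the classical-forcefield backend; the minimized forcefield energy is
    stored as the screening energy.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from .energy_backends import ForceFieldBackend

    config = config or PipelineConfig()
    backend = backend or ForceFieldBackend()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = config.seed
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=config.n_conformers, params=params)
    records = []
    for cid in cids:
        energy, _ = backend.optimize(mol, cid)
        records.append(
            ConformerRecord(
                conf_id=int(cid),
                symbols=[a.GetSymbol() for a in mol.GetAtoms()],
                coords=np.array(mol.GetConformer(cid).GetPositions()),
                energy=energy,
                provenance={"smiles": smiles, "mol": mol, "backend": backend.name},
            )
        )
    n_failed = config.n_conformers - len(records)
    if n_failed:
        for r in records:
            r.provenance["embedding_failures"] = n_failed
    return records


def _heavy_rmsd(a: ConformerRecord, b: ConformerRecord, heavy: np.ndarray) -> float:
    """Heavy-atom RMSD after optimal (Kabsch) superposition."""
    P = a.coords[heavy] - a.coords[heavy].mean(axis=0)
    Q = b.coords[heavy] - b.coords[heavy].mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))


def diversity_select(records: Sequence[ConformerRecord],
                     config: PipelineConfig | None = None,
                     duplicate_rmsd: float = 1.0e-3) -> list[ConformerRecord]:
    """Greedy max-min RMSD selection of at most ``max_selected`` conformers.

    Starts from the lowest-energy record; each round adds the record
    farthest (heavy-atom RMSD after superposition) from the current
    selection.  Exact duplicates (RMSD below ``duplicate_rmsd``) never
    enter twice.
    """
    config = config or PipelineConfig()
    pool = [r for r in records if r.coords is not None]
    if not pool:
        return []
    heavy = np.array([i for i, s in enumerate(pool[0].symbols) if s != "H"])
    order = sorted(range(len(pool)), key=lambda i: (pool[i].energy if pool[i].energy is not None else np.inf, i))
    selected = [order[0]]
    min_d = np.array([_heavy_rmsd(pool[order[0]], r, heavy) for r in pool])
    while len(selected) < min(config.max_selected, len(pool)):
        cand = int(np.argmax(min_d))
        if min_d[cand] <= duplicate_rmsd:
            break
        selected.append(cand)
        d = np.array([_heavy_rmsd(pool[cand], r, heavy) for r in pool])
        min_d = np.minimum(min_d, d)
    return [pool[i] for i in sorted(selected)]


def filter_by_energy(records: Sequence[ConformerRecord],
                     config: PipelineConfig | None = None,
                     pyranosyl: bool = False) -> list[ConformerRecord]:
    """Keep records within the screening-energy window above the minimum.

    The window is ``energy_cutoff`` (default 40 kJ/mol) or
    ``pyranosyl_cutoff`` (default 80 kJ/mol) when ``pyranosyl`` is set;
    the minimum-energy record always survives.
    """
    config = config or PipelineConfig()
    pool = [r for r in records if r.energy is not None]
    if not pool:
        return []
    cutoff = config.pyranosyl_cutoff if pyranosyl else config.energy_cutoff
    e0 = min(r.energy for r in pool)
    return [r for r in pool if r.energy - e0 <= cutoff + 1e-12]


def scale_frequencies(lines: Spectrum, factor: float = 0.975) -> Spectrum:
    """Multiply line positions by the harmonic scaling factor; intensities kept."""
    if lines.kind != "line-list":
        raise ValueError("frequency scaling applies to line lists")
    return Spectrum(lines.positions * factor, lines.intensities, "line-list")


def broaden(lines: Spectrum, width: float = 20.0, grid: np.ndarray | None = None,
            width_is_fwhm: bool = True) -> Spectrum:
    """Convolve a stick spectrum with unit-area Gaussians onto a grid.

    ``width`` is the FWHM (the convention in the ion-spectroscopy
    literature) unless ``width_is_fwhm`` is False, in which case it is
    sigma.  The trace integrates to the summed line intensity up to grid
    truncation.
    """
    if lines.kind != "line-list":
        raise ValueError("broadening applies to line lists")
    if width <= 0:
        raise ValueError("width must be positive")
    if grid is None:
        grid = PipelineConfig().grid()
    sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0))) if width_is_fwhm else width
    trace = np.zeros_like(grid)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for pos, inten in zip(lines.positions, lines.intensities):
        trace += inten * norm * np.exp(-((grid - pos) ** 2) / (2.0 * sigma**2))
    return Spectrum(grid, trace, "trace")


def ensemble_spectrum(records: Sequence[ConformerRecord],
                      traces: Sequence[Spectrum],
                      T: float = thermo.IR_TEMPERATURE,
                      fractions: Sequence[float] | None = None) -> Spectrum:
    """Population-weighted composite trace.

    Weights come from Boltzmann factors of the records' free energies
    (falling back to electronic energies) at temperature ``T``, or from
    explicit ``fractions`` (e.g. for two-species mixture tests).
    Mismatched grids are resampled onto the first trace's grid.
    """
    if not traces:
        raise ValueError("at least one trace required")
    grid = traces[0].positions
    resampled = [t if np.array_equal(t.positions, grid) else t.resample(grid) for t in traces]
    if fractions is not None:
        w = np.asarray(fractions, dtype=float)
        if w.size != len(traces):
            raise ValueError("one fraction per trace required")
        w = w / w.sum()
    else:
        g = [r.best_energy() for r in records]
        if len(g) != len(traces) or any(v is None for v in g):
            raise ValueError("records with energies must pair 1:1 with traces")
        w = thermo.boltzmann_weights(g, T)
    total = np.zeros_like(grid)
    for wi, t in zip(w, resampled):
        total += wi * t.intensities
    return Spectrum(grid, total, "trace")


def match_score(computed: Spectrum, experimental: Spectrum,
                range_: tuple[float, float] = WORKING_RANGE,
                metric: str = "cosine") -> float:
    """Similarity of two traces over a wavenumber range, in [-1, 1].

    Both traces are resampled to a common 1 cm^-1 grid over the overlap
    of ``range_`` with both spectra, max-normalized, and compared by
    cosine similarity (default) or Pearson correlation.  Invariant to
    uniform intensity scaling of either input.
    """
    lo = max(range_[0], computed.range[0], experimental.range[0])
    hi = min(range_[1], computed.range[1], experimental.range[1])
    if hi <= lo:
        raise ValueError("empty overlap range between spectra")
    grid = np.arange(lo, hi + 0.5, 1.0)
    a = computed.resample(grid).intensities
    b = experimental.resample(grid).intensities
    if a.max() > 0:
        a = a / a.max()
    if b.max() > 0:
        b = b / b.max()
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(np.dot(a, b) / (na * nb))
    if metric == "pearson":
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])
    raise ValueError(f"unknown metric {metric!r}")


#: diagnostic windows (cm^-1) used by classify_ion_type
DEFAULT_BAND_TABLE = {
    "oxocarbenium_stretch": (1575.0, 1625.0),  # C1=O5+ stretch ~1600
    "acetyl_co": (1770.0, 1830.0),  # intact ester C=O ~1800
    "dioxolenium_stretch": (1525.0, 1575.0),  # O-C=O+ stretch ~1550
    "dioxolenium_bend": (1475.0, 1525.0),  # O-C=O+ bend ~1500
    "ring_opened_co": (1730.0, 1790.0),  # regenerated carbonyl
}


def _band_presence(trace: Spectrum, window: tuple[float, float],
                   rel_threshold: float) -> tuple[bool, float | None]:
    lo, hi = window
    mask = (trace.positions >= lo) & (trace.positions <= hi)
    if not np.any(mask):
        raise ValueError(f"trace does not cover diagnostic window {window}")
    height = rel_threshold * trace.intensities.max()
    peaks, props = find_peaks(trace.intensities, height=height)
    in_win = [p for p in peaks if mask[p]]
    if not in_win:
        # a broad band can put the window on a shoulder; accept a plateau
        # only if the window holds the local maximum above threshold
        return False, None
    best = max(in_win, key=lambda p: trace.intensities[p])
    return True, float(trace.positions[best])


def classify_ion_type(trace: Spectrum, band_table: dict | None = None,
                      rel_threshold: float = 0.05) -> IonAssignment:
    """Assign the ion structure from diagnostic band presence.

    Rules:

    * oxocarbenium: C1=O5+ stretch (~1600) AND acetyl C=O (~1800) AND
      no dioxolenium stretch (~1550);
    * dioxolenium: stretch (~1550) AND bend (~1500) AND no acetyl C=O;
    * ring-opened: dioxolenium stretch AND a carbonyl in 1730-1790;
    * otherwise mixed/indeterminate.

    Peaks are local maxima above ``rel_threshold`` of the trace maximum.
    """
    if trace.kind != "trace":
        raise ValueError("classification requires a broadened trace")
    table = band_table or DEFAULT_BAND_TABLE
    evidence = {}
    for name, window in table.items():
        present, pos = _band_presence(trace, window, rel_threshold)
        evidence[name] = {"present": present, "position": pos}

    def has(name: str) -> bool:
        return evidence[name]["present"]

    if has("dioxolenium_stretch") and has("ring_opened_co"):
        label = "ring-opened"
    elif has("dioxolenium_stretch") and has("dioxolenium_bend") and not has("acetyl_co"):
        label = "dioxolenium"
    elif has("oxocarbenium_stretch") and has("acetyl_co") and not has("dioxolenium_stretch"):
        label = "oxocarbenium"
    else:
        label = "mixed/indeterminate"
    return IonAssignment(label=label, evidence=evidence)


# --------------------------------------------------------------------------
# end-to-end driver
# --------------------------------------------------------------------------

def run_pipeline(smiles: str, config: PipelineConfig | None = None,
                 pyranosyl: bool = False, backend=None) -> dict:
    """Full simulation for one cation: search -> select -> filter ->
    frequencies -> scale -> broaden -> Boltzmann ensemble.

    Returns a dict with the stage ensembles ("generated", "selected",
    "filtered"), per-conformer broadened traces ("traces"), the
    composite "spectrum", and a "stages" count summary.
    """
    from .energy_backends import ForceFieldBackend

    config = config or PipelineConfig()
    backend = backend or ForceFieldBackend()
    generated = conformer_search(smiles, config, backend)
    selected = diversity_select(generated, config)
    filtered = filter_by_energy(selected, config, pyranosyl)
    mol = filtered[0].provenance.get("mol") if filtered else None
    traces = []
    for rec in filtered:
        freqs, intens, n_imag = backend.frequencies(mol, rec.conf_id)
        rec.n_imaginary = n_imag
        real = freqs > 0
        rec.frequencies, rec.intensities = freqs[real], intens[real]
        tr = thermo.thermo_corrections(
            rec.frequencies, T=config.temperature, scheme="quasi-harmonic"
        )
        rec.gibbs = tr.apply(rec.energy)
        lines = scale_frequencies(
            Spectrum(rec.frequencies, rec.intensities), config.scale_factor
        )
        traces.append(
            broaden(lines, config.broaden_width, config.grid(), config.width_is_fwhm)
        )
    keep = [i for i, r in enumerate(filtered) if not r.has_imaginary] or list(range(len(filtered)))
    spectrum = ensemble_spectrum(
        [filtered[i] for i in keep], [traces[i] for i in keep], config.temperature
    ) if traces else None
    return {
        "generated": generated,
        "selected": selected,
        "filtered": filtered,
        "traces": traces,
        "spectrum": spectrum,
        "stages": {
            "generated": len(generated),
            "selected": len(selected),
            "filtered": len(filtered),
        },
    }


# --------------------------------------------------------------------------
# two-column TSV I/O
# --------------------------------------------------------------------------

def write_spectrum_tsv(spec: Spectrum, path) -> None:
    header = "# kind=%s\n# wavenumber_cm-1\tintensity\n" % spec.kind
    with open(path, "w") as fh:
        fh.write(header)
        for p, i in zip(spec.positions, spec.intensities):
            fh.write(f"{p:.4f}\t{i:.8g}\n")


def read_spectrum_tsv(path) -> Spectrum:
    kind = "trace"
    pos, inten = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "kind=" in line:
                    kind = line.split("kind=")[1].strip()
                continue
            a, b = line.split("\t")
            pos.append(float(a))
            inten.append(float(b))
    return Spectrum(np.array(pos), np.array(inten), kind)
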