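# condensir

Analysis toolkit for the question of how water behaves inside
biomolecular condensates: do protein–water hydrogen bonds live longer
in the dense (droplet) phase of a liquid–liquid phase-separated
protein solution than around dispersed chains?  The package implements
the full computational chain used to answer this for an intrinsically
disordered low-complexity domain (FUS LC-like systems):

1. **Phase classification** — chains in a periodic simulation box are
   clustered as *condensed* whenever any atom of one chain lies within
   0.3 nm of any atom of another; the largest connected cluster is the
   condensate, the rest is the dispersed phase.
2. **H-bond survival dynamics** — boolean occupancy `h_ij(t)` of
   amide-oxygen/water H-bonds gives the survival autocorrelation

       C(t) = ⟨Σ_ij h_ij(t0) h_ij(t0+t)⟩ / ⟨Σ_ij h_ij(t0)²⟩,

   which, after removal of the equilibrium baseline, is fitted with a
   simplex-constrained triple exponential
   `Σ_n A_n exp(−t/τ_n)` (`A_n ≥ 0`, `Σ A_n = 1`).  The reported
   H-bond lifetime is the amplitude-weighted mean `τ = Σ A_n τ_n`,
   i.e. the integral of the unit-normalized fit.
3. **Amide I exciton spectra** — site frequencies from a linear C=O
   bond-length map `ω_i = Ω₀ − S (r_i − r₀)` (Ω₀ = 1655 cm⁻¹,
   r₀ = 1.229 Å, S = 400 cm⁻¹/Å, −19 cm⁻¹ upstream of prolines),
   nearest-neighbour couplings from a periodic (φ, ψ) dihedral map,
   longer-range couplings from transition dipole coupling
   `β ∝ [ê_i·ê_j − 3(ê_i·n̂)(ê_j·n̂)]/r³`; diagonalization plus
   Lorentzian convolution (HWHM 6 cm⁻¹) yields the linear IR band.
4. **2D IR spectral diffusion** — the center line slope CLS(Tw) of the
   ground-state bleach over the 1618–1685 cm⁻¹ pump window (and the
   nodal line slope as a cross-check), fitted with
   `CLS(Tw) = CLS₀ exp(−Tw/τ_specdiff)`; vibrational relaxation from
   integrated bleach volumes via `A₀ exp(−Tw/τ_VER) + y₀`.

Every stage is validated against synthetic inputs with exactly known
ground truth: a two-state telegraph process for H-bond kinetics (exact
analytic ACF), a joint-Gaussian Kubo-style 2D lineshape (closed-form
CLS), ideal-geometry peptide backbones, and constructed
droplet-plus-dispersed configurations.

The fit-shaped stages are scikit-learn style estimators
(`TriExponentialDecay`, `ExponentialDecay`, `ChainPhaseClassifier`)
with `fit`/`predict` and trailing-underscore attributes; module-level
functions (`fit_triexp`, `cluster_chains`, …) are thin wrappers.

## Worked example

Generate a droplet of 6 chains plus 3 dispersed chains in a 16 nm
periodic box, attach telegraph H-bond kinetics whose true mean
lifetimes are 1.4 ps (condensed) and 1.0 ps (dispersed) — a 40%
slowdown — and run the full classify → ACF → fit pipeline:

```python
import condensir as cn
from condensir.io import write_frame_table

frame = cn.gen_droplet_system(n_condensed=6, n_dispersed=3,
                              box=160.0, min_gap=10.0, seed=2)
write_frame_table(frame, "system.dat")

cfg = cn.RunConfig(
    structure_path="system.dat", output_dir="out",
    telegraph_rates={"condensed": (1/2.8, 1/2.8),   # 1/(k_on+k_off) = 1.4 ps
                     "dispersed": (0.5, 0.5)},      # 1.0 ps
    seed=17)
report = cn.run_pipeline(cfg)
print(report["results"]["condensed"]["mean_lifetime_ps"])   # 1.395969746596
print(report["results"]["dispersed"]["mean_lifetime_ps"])   # 1.017012394665
print(report["results"]["lifetime_ratio_condensed_over_dilute"])  # 1.372618223651
```

The recovered lifetimes agree with the constructed 1.4 and 1.0 ps to
within sampling error, and the condensed/dilute ratio reproduces the
built-in 40% slowdown.  The same flow is available from the shell:

```sh
condensir simulate --kind kubo --seed 1 --out cube.dat
condensir cls cube.dat --out cls.json
# CLS0 = 0.9174, tau_specdiff = 3.0003 ps   (generator used tau_c = 3 ps)
condensir ver cube.dat --out ver.json
# tau_VER = 0.5500 ps                       (generator used T1 = 0.55 ps)
```

Other subcommands: `classify`, `hbonds`, `spectrum`, `pipeline`.

## Frame table format

Plain-text trajectory frames use the grammar

```
file    := header line*
header  := "# condensir-frame 1" ["# box BX BY BZ"] "# periodic BOOL" comment
line    := ATOM_ID CHAIN_ID RESID ROLE NAME X Y Z
ROLE    := amide_O | amide_H | water_O | water_H | other
```

with coordinates in Å; water molecules carry chain id −1.  PDB is
accepted for structures; 2D cubes use a single text file with pump,
probe and waiting-time axes in `#` header lines followed by one matrix
block per waiting time (`condensir.io`).

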