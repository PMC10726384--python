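import numpy as np
import pytest

from condensir import KuboParams, PeptideSpec, gen_kubo_2dspectra, gen_peptide_chain


@pytest.fixture
def kubo_cube_factory():
    """Noise-free joint-Gaussian 2D IR cube with well-separated lobes."""
    def make(inhomogeneous_width=10.0, homogeneous_width=0.5,
             correlation_time=3.0, population_lifetime=0.55,
             waiting_times=(0.0, 0.3, 0.6, 0.9), anharmonic_shift=100.0,
             noise_sd=0.0, seed=0):
        return gen_kubo_2dspectra(KuboParams(
            center_frequency=1650.0,
            inhomogeneous_width=inhomogeneous_width,
            correlation_time=correlation_time,
            homogeneous_width=homogeneous_width,
            anharmonic_shift=anharmonic_shift,
            population_lifetime=population_lifetime,
            waiting_times=np.asarray(waiting_times, dtype=float),
            pump_axis=np.arange(1610.0, 1691.0),
            probe_axis=np.arange(1490.0, 1701.0),
            noise_sd=noise_sd, seed=seed))
    return make


@pytest.fixture
def helix():
    return gen_peptide_chain(PeptideSpec(
        n_residues=12, dihedrals=np.tile([-57.0, -47.0], (12, 1))))
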