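# origamikin

Assembly kinetics of membrane-anchored DNA-origami superstructures, on
synthetic data.

DNA-origami monomers anchored to a supported lipid bilayer (SLB) diffuse in
two dimensions (D ≈ 0.2 µm²/s) and cross-link into higher-order assemblies
when connector oligonucleotides are added. Two connector families behave very
differently: *scaffold connectors* hybridize directly to scaffold loops — one
unique binding register, orientation-specific, slow — while *repeat
connectors* (oligo-T) bind short A₇ staple extensions at any of several
alignment registers ("reading frames"), which multiplies the effective
association rate. `origamikin` provides everything needed to quantify this
comparison end to end without a microscope:

- **`connectors`** — connector designs and the effective-on-rate model
  `k_eff = k_base · n_frames · hairpin_accessibility · valence`,
  with `n_frames = max(0, L_sticker − L_docking + 1)`.
- **`simulate`** — stochastic 2D diffusion–aggregation of monomers with
  connector-dependent edge-binding rules (orientation-specific/linear for
  scaffold, promiscuous/branching for repeat), rigid clusters with
  size-dependent mobility D_n.
- **`render`** — synthetic TIRF camera movies at the study's acquisition
  geometry (130 nm pixels, 30 Hz, 300-frame windows, laser shuttered between
  windows): integrated Gaussian PSF, Poisson shot noise, Gaussian read noise,
  16-bit TIFF output with JSON metadata sidecars.
- **`correlate`** — the temporal image-correlation readout: the correlation
  parameter C (pixel-averaged lag-1 temporal autocovariance of detrended
  intensity, normalized by the squared offset-corrected mean) rises as
  monomers oligomerize into fewer, brighter particles and collapses once
  assemblies immobilize; a logistic-decay fit of C(t) yields the
  characteristic assembly timescale t½.
- **`spt`** — single-particle tracking (local-maxima localization,
  mutual-nearest-neighbor linking, MSD = 4Dτ fitting) to verify mobility
  before cross-linking and immobilization after.
- **`experiment`** — condition sweeps (scaffold ± linker, sticker lengths
  6–9 nt, all-T lengths 14–80 nt, mixes) with per-replicate fit reports and
  fitted/acquired bookkeeping.

## Worked example

Two identical repeat-connector conditions whose effective link rates differ
by 10× — the in-silico analogue of comparing an efficient connector design
against a sluggish one:

```python
import numpy as np
import origamikin as ok
from origamikin.simulate import log_schedule

conn = ok.ConnectorSpec(kind="repeat", total_length=40, sticker_length=9,
                        spacer_length=22)
base = ok.SimConfig(domain_side=8.32, n_monomers=576, dt=0.08,
                    capture_radius=0.2, branch_probability=0.3,
                    orientation_rule="any")
conditions = (
    ok.Condition(label="fast", connectors=(conn,),
                 sim_overrides={"link_rate": 0.01, "total_time": 1210.0,
                                "observation_schedule": log_schedule(10.0, 1200.0, 24, 64)}),
    ok.Condition(label="slow", connectors=(conn,),
                 sim_overrides={"link_rate": 0.001, "total_time": 6010.0,
                                "observation_schedule": log_schedule(10.0, 6000.0, 24, 64)}),
)
config = ok.ExperimentConfig(conditions=conditions, base_sim=base,
                             optics=ok.OpticsConfig(frames_per_window=64),
                             output_dir="out", master_seed=20260923,
                             n_replicates=10, write_stacks=False,
                             first_window_offset=0.0)
fast, slow = ok.run_experiment(config)
print("fast t_half:", np.round(fast.t_half_values, 1))
print("slow t_half:", np.round(slow.t_half_values, 1))
print("ratio:", slow.t_half_values.mean() / fast.t_half_values.mean())
```

Output:

```
fast t_half: [342.1  80.2  42.9 176.5  65.1 188.3 165.1  52.9 162.2  65.1]
slow t_half: [1150.1  992.6 1550.9  534.8 1196.3 1695.7 1357.8  878.8 1248.3  986.6]
ratio: 8.648576384517739
```

Each number is a per-replicate characteristic assembly timescale in seconds —
the midpoint of the logistic decay of the correlation parameter. The mean
timescales differ by a factor of ≈ 8.6, recovering the imposed 10× rate
difference within the statistical scatter of ten replicates; per-replicate
correlation time courses show the expected rise (oligomerization into fewer,
brighter mobile particles) followed by a fall to baseline (immobilization).

The same pipeline is available from the shell:

```bash
origamikin simulate --config sim.yaml --seed 3 --out traj.npz
origamikin render --trajectory traj.npz --seed 4 --out-dir stacks/
origamikin correlate stacks/*.tif --out timecourse.csv
origamikin fit --timecourse timecourse.csv --out fit.json
origamikin validate --seed 0 --out sensitivity.csv
```

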