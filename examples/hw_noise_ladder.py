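"""Prediction uncertainty versus noise in the training data.

Regenerates the same Harris-Wilson dataset at increasing measurement
noise and calibrates each.  The half-height width of the alpha
marginal — the method's uncertainty measure — grows with the data
noise; at very high noise the nontrivial solution stops being
identifiable and the marginal collapses onto the trivial value
alpha = 1.

Run time: about ten minutes on one CPU core.
"""

from neurocalib import density as de
from neurocalib.hw_synthesis import SyntheticHWSpec, generate
from neurocalib.neural_calibration import TrainConfig, run_multi_init, samples_frame
from neurocalib.problems import HWProblem

for sigma in (0.0, 0.1, 0.5, 1.5):
    network, traj, _ = generate(SyntheticHWSpec(seed=5, sigma=sigma))
    problem = HWProblem(network, traj)
    cfg = TrainConfig(epochs=1200, batch_size=1, n_initializations=8, seed=7)
    df = samples_frame(run_multi_init(problem, problem.default_net_config(), cfg))
    md = de.marginal(df["alpha"].to_numpy(), losses=df["loss"].to_numpy(),
                     parameter_name="alpha")
    peaks = de.peak_widths(md)
    mode = de.summarize(md)["mle"]
    print(f"sigma = {sigma:4.2f}:  alpha mode {mode:5.2f},  "
          f"mean peak width {peaks.mean_width:.3f}  "
          f"(width SD {peaks.width_sd:.3f}, {peaks.n_peaks} peak(s))")

print("\nWider peaks = less certain estimates.  As the noise grows the "
      "mean width rises and the dominant mode drifts from the true "
      "alpha = 1.2 toward the trivial solution alpha = 1, which is all "
      "that remains identifiable at the highest noise level.")
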