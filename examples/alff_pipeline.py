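"""Compute ALFF maps from a simulated resting-state series and aggregate
them per region.

Simulates a BOLD-like 4-D series (TR 2.5 s, 200 time points) in which
three ROIs carry low-frequency sinusoids of amplitude 1.0, 2.0 and 0.5
on top of noise and drift, then recovers the amplitudes with the ALFF
pipeline (detrend, FFT, mean in-band amplitude over 0.01-0.08 Hz).  The
per-region means should scale like the assigned amplitudes."""

from paareg import compute_alff, make_roi_labels, roi_mean, simulate_bold


def main():
    labels = make_roi_labels((16, 16, 16), regions=("LMTG", "RPLC", "RC"))
    series = simulate_bold(labels, {"LMTG": 1.0, "RPLC": 2.0, "RC": 0.5},
                           n_t=200, tr=2.5, noise_sigma=0.1, seed=7)
    alff_map = compute_alff(series, band=(0.01, 0.08))
    table = roi_mean(alff_map, labels, subject_id="demo")
    print(table.to_string(index=False))
    ratios = table.set_index("region")["mean_alff"]
    print(f"\nRPLC / LMTG amplitude ratio: {ratios['RPLC'] / ratios['LMTG']:.3f} "
          "(simulated amplitude ratio 2.0; the white-noise amplitude floor adds "
          "to every region, pulling the observed ratio toward 1)")


if __name__ == "__main__":
    main()
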