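"""Recover a known rigid motion of a 3-D phantom with principal-axis
registration, then polish the estimate with intensity-metric refinement.

Builds the standard 64-cube asymmetric phantom, moves it by a known
six-parameter motion plus 5% noise, and registers the pair.  The printed
lines compare the true motion with the closed-form estimate and the
refined estimate; errors are in mm and degrees, and NCC is the
normalized cross-correlation with the reference after alignment (1.0 is
a perfect match)."""

import numpy as np

from paareg import (
    PhantomSpec,
    RigidParams,
    make_pair,
    make_phantom,
    refine,
    register_paa,
)


def describe(tag, params, truth, ncc_value):
    t_err = np.abs(params.translation - truth.translation).max()
    a_err = np.rad2deg(np.abs(params.angles - truth.angles)).max()
    print(f"{tag:>10}: l = ({params.l1:+.2f}, {params.l2:+.2f}, {params.l3:+.2f}) mm, "
          f"angles = ({np.rad2deg(params.m4):+.2f}, {np.rad2deg(params.m5):+.2f}, "
          f"{np.rad2deg(params.m6):+.2f}) deg | max err {t_err:.3f} mm / {a_err:.3f} deg"
          f" | NCC {ncc_value:.4f}")


def main():
    phantom = make_phantom(PhantomSpec())
    truth = RigidParams(4.0, -3.0, 2.0,
                        np.deg2rad(8.0), np.deg2rad(-12.0), np.deg2rad(15.0))
    reference, floating, _ = make_pair(phantom, truth,
                                       noise_sigma=0.05 * phantom.data.max(), seed=42)

    paa = register_paa(reference, floating)
    refined = refine(reference, floating, paa.params, metric="ncc")

    print("known truth: l = (+4.00, -3.00, +2.00) mm, "
          "angles = (+8.00, -12.00, +15.00) deg")
    describe("PAA", paa.params, truth, paa.similarity_after)
    describe("refined", refined.params, truth, refined.similarity_after)
    print(f"closed-form PAA used {paa.iterations} iteration; "
          f"refinement used {refined.iterations} metric evaluations.")


if __name__ == "__main__":
    main()
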