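"""Size-exclusion molecular-weight calibration and estimation.

Fits the polynomial relating log10 molecular weight to retention time
through a pullulan-like standard ladder, then converts sample retention
times to molecular weights, flagging extrapolation outside the standards.
"""

from fucokit import activity as act

standards = [  # (retention time min, MW Da), synthetic ladder
    (10.0, 805000.0),
    (11.5, 348000.0),
    (13.0, 113000.0),
    (14.5, 47100.0),
    (16.0, 21100.0),
    (17.5, 9600.0),
    (19.0, 1320.0),
    (20.5, 305.0),
]

cal = act.hpsec_calibrate(standards, degree=3)
print(f"degree {cal.degree} fit over {cal.rt_min}-{cal.rt_max} min, "
      f"monotone decreasing: {cal.monotone_decreasing}")

for rt in (12.0, 18.0, 21.5):
    est = act.estimate_mw(cal, rt)
    flag = "  (extrapolated)" if est.extrapolated else ""
    print(f"rt = {rt:5.1f} min  ->  MW ~ {est.mw_da:,.0f} Da{flag}")

# Later-eluting species are smaller; estimates beyond the standard window
# carry an extrapolation flag and should be treated as rough.
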