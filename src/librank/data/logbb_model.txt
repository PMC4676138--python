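# Blood-brain-barrier permeation (logBB) regression model.
# Linear terms plus GFA truncated-power spline terms; <a - x> = max(0, a - x).
# Format: "intercept VALUE" | "linear NAME COEF" |
#         "spline_below NAME KNOT COEF"  (COEF * max(0, KNOT - x)) |
#         "spline_above NAME KNOT COEF"  (COEF * max(0, x - KNOT))
intercept 1.2827
linear AlogP98 0.17977
linear DPSA1 -0.0033777
linear Num_H_Acceptors -0.18676
linear S_sssN 0.1557
spline_below S_ssCH2 4.6743 -0.022135
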