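# Default force-field parameter file for the Bis-GMA/TEGDMA coarse-grain model.
#
# SYNTHETIC STAND-IN TABLE.  The published Martini 3 nonbonded interaction
# matrix is distributed with the Martini force-field files and is not bundled
# here.  The pair coefficients below were constructed in-package from the
# Martini 3 size-class sigmas (0.47 / 0.41 / 0.34 nm for regular / small /
# tiny self-interactions, intermediate values for cross-size pairs) and a
# chemistry-informed epsilon ladder (geometric-mean combination with a
# polarity-mismatch reduction).  They give physically reasonable condensed
# phases for testing and demonstration, but quantitative production work
# should substitute the published Martini 3 matrix in this same file format.
#
# Format: sections [options], [masses], [pairs].
#   pairs:  TYPE1 TYPE2 sigma_nm epsilon_kJmol
#   masses: TYPE mass_amu
# '#' starts a comment.

[options]
cutoff_nm 1.1
shift yes

[masses]
# standard Martini masses by size class: regular 72, small 54, tiny 36 amu
SC4   54
N4a   72
TP1   36
TN2a  36
TC5   36
SC2   54
SN3a  54

[pairs]
SC4   SC4      0.410    2.900
SC4   N4a      0.440    3.060
SC4   TP1      0.375    3.002
SC4   TN2a     0.375    2.955
SC4   TC5      0.375    2.664
SC4   SC2      0.410    2.630
SC4   SN3a     0.410    2.952
N4a   N4a      0.470    3.900
N4a   TP1      0.405    3.849
N4a   TN2a     0.405    3.321
N4a   TC5      0.405    2.802
N4a   SC2      0.440    2.758
N4a   SN3a     0.440    3.532
TP1   TP1      0.340    4.300
TP1   TN2a     0.340    3.264
TP1   TC5      0.340    2.742
TP1   SC2      0.375    2.692
TP1   SN3a     0.375    3.479
TN2a  TN2a     0.340    3.200
TN2a  TC5      0.340    2.711
TN2a  SC2      0.375    2.675
TN2a  SN3a     0.375    3.200
TC5   TC5      0.340    2.600
TC5   SC2      0.375    2.570
TC5   SN3a     0.375    2.706
SC2   SC2      0.410    2.700
SC2   SN3a     0.410    2.666
SN3a  SN3a     0.410    3.400
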