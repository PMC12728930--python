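TEMPLATE AFUC
SUGAR FUC
ANOMERIC alpha
RING_SIZE 6
STEREO C1 -1
STEREO C2 -1
STEREO C3 +1
STEREO C4 +1
STEREO C5 +1
ATOM O5   O  Os   -0.4700
ATOM C1   C  Cg    0.1000
ATOM C2   C  Cg    0.1700
ATOM C3   C  Cg    0.1700
ATOM C4   C  Cg    0.1700
ATOM C5   C  Cg    0.1700
ATOM O1   O  Oh   -0.6000
ATOM HO1  H  Ho    0.4200
ATOM H1   H  Hc    0.0300
ATOM O2   O  Oh   -0.6000
ATOM HO2  H  Ho    0.4200
ATOM H2   H  Hc    0.0300
ATOM O3   O  Oh   -0.6000
ATOM HO3  H  Ho    0.4200
ATOM H3   H  Hc    0.0300
ATOM O4   O  Oh   -0.6000
ATOM HO4  H  Ho    0.4200
ATOM H4   H  Hc    0.0300
ATOM H5   H  Hc    0.0300
ATOM C6   C  Cg    0.1700
ATOM H61  H  Hc    0.0300
ATOM H62  H  Hc    0.0300
ATOM H63  H  Hc    0.0300
BOND C1 C2
BOND C1 H1
BOND C1 O1
BOND C2 C3
BOND C2 H2
BOND C2 O2
BOND C3 C4
BOND C3 H3
BOND C3 O3
BOND C4 C5
BOND C4 H4
BOND C4 O4
BOND C5 C6
BOND C5 H5
BOND C6 H61
BOND C6 H62
BOND C6 H63
BOND O1 HO1
BOND O2 HO2
BOND O3 HO3
BOND O4 HO4
BOND O5 C1
BOND O5 C5
END
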