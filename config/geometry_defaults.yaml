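# Default fiber-skeleton geometry constants; override per segment as needed.
# Load with fiberhop.load_geometry("config/geometry_defaults.yaml", L=<um>).
L: 4.0            # probed segment length, um
N_F: 68           # parallel fibers per skeleton
d_F: 26.0         # conductive-core diameter of one fiber, nm
N_C: 30           # parallel conduction channels per fiber
delta_site: 0.78  # assumed cofactor center-to-center spacing, nm
h: 300.0          # skeleton height, nm (Joule-heating estimate)
w: 4.0            # skeleton width, um
k_protein: 0.3    # protein thermal conductivity, W/mK
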