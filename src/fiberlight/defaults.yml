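# Default model parametrization.  Lengths in μm, times in fs.

c_0: 0.299792458          # speed of light in vacuum (μm/fs)

# Tissue properties
ntissue: 1.36             # refractive index of cortical tissue
mu_a: 0.00006             # absorption coefficient (1/μm)
mu_s: 0.0211              # scattering coefficient (1/μm)
g: 0.86                   # anisotropy factor <cos theta>

# Optical fiber
NA: 0.37                  # numerical aperture
opt_radius: 100           # radius of the emission surface (μm)

# Final volume
xymax: 700                # maximum xy dimension (μm)
dxy: 5                    # step size in the xy plane (μm)
zmax: 700                 # maximum z dimension (μm)
dz: 5                     # step size along depth (μm)

# Calculation of the scattered pencil beam
rho_exp_min: 1            # start of radial log-sampling (μm); subtracted so the axis starts at 0
n_rho_smpls: 20           # number of radial samples
tau_min: 5                # lower multipath-time integration bound (fs)
tau_max: 10000            # upper multipath-time integration bound (fs)
n_tau_smpls: 100          # number of multipath-time samples
mu_tau: eq4               # moment parametrization: eq4 | table1_Lutomirski | table1_vandeHulst | eq4_precise_sigma

# Angular convolution of the scattered pencil beam
nsteps_theta: 24
nsteps_phi: 24

# Disk convolution
dxy_direct_disk: 3        # step size for the direct component (μm)
dxy_scattered_disk: 10    # step size for the scattered component (μm)
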