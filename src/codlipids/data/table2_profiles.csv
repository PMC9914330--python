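fatty_acid,norway_mean,norway_sd,iceland_mean,iceland_sd,alaska_mean,alaska_sd,p_species,p_origin
C14:0,1.82,0.34,1.87,0.44,1.23,0.20,<0.001,0.686
C15:0,0.31,0.03,0.34,0.04,0.28,0.03,<0.001,0.024
anteiso-C16:0,0.14,0.08,0.18,0.11,0.13,0.01,0.398,0.325
C16:0,20.5,1.44,24.0,0.86,21.9,0.22,0.487,<0.001
C17:0,0.21,0.15,0.23,0.15,0.20,0.01,0.579,0.586
C18:0,4.72,0.45,5.07,0.62,5.337,0.04,0.006,0.059
C16:1 *cis*-9,1.24,0.75,1.86,0.62,1.36,0.18,0.069,<0.001
C16:1 *cis*-7,0.68,0.50,0.63,0.38,0.40,0.03,0.017,0.721
C17:1 *cis*-9,0.06,0.03,0.09,0.05,0.13,0.08,0.041,0.004
C18:1 *cis*-13,0.40,0.04,0.51,0.43,0.36,0.23,0.261,0.258
C18:1 *cis*-11,3.44,0.40,3.63,0.55,3.26,0.51,0.066,0.276
C18:1 *cis*-9,7.03,0.59,9.26,0.88,8.26,0.69,0.588,<0.001
C20:1 *cis*-13,1.35,0.52,1.95,1.26,0.15,0.08,0.012,0.200
C20:1 *cis*-11,1.69,0.33,2.43,1.12,2.34,0.24,0.212,0.006
C22:1 *cis*-11,0.35,0.21,0.53,0.38,0.45,0.22,0.952,0.096
C16:2 n-4,0.65,0.08,0.62,0.08,0.55,0.05,<0.001,0.329
C18:2 n-6,1.02,0.12,1.20,0.47,1.26,0.35,0.111,0.087
C20:4 n-6,2.44,0.35,2.07,0.43,2.20,0.64,0.729,0.038
C16:4 n-3,0.15,0.11,0.23,0.13,0.17,0.05,0.489,0.069
C18:3 n-3,0.25,0.04,0.26,0.14,0.23,0.11,0.451,0.749
C18:4 n-3,0.54,0.09,0.63,0.08,0.53,0.22,0.150,0.045
C20:4 n-3,0.42,0.22,0.37,0.24,0.35,0.19,0.293,0.300
C20:5 n-3 (EPA),20.1,1.91,15.2,1.57,15.1,1.54,<0.001,<0.001
C22:5 n-3,2.03,0.88,0.79,0.46,1.22,0.63,0.291,<0.001
C22:6 n-3 (DHA),29.5,2.89,28.2,2.34,33.4,3.26,<0.001,0.177
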