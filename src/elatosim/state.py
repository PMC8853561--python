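"""Layout of the packed simulation state vector.

One flat float64 vector carries every integrated quantity: the stand pools
(per m2 ground), the ten per-stem aphid stage abundances, and the cumulative
boundary-flux ledgers used by the mass-balance audit.
"""

# stand pools (kg m-2 ground, stems m-2)
I_NSTEMS = 0
I_CFOL = 1      # foliage structural C
I_CWOOD = 2     # stem + branch wood structural C
I_CROOT = 3     # fine-root structural C
I_CLE = 4       # foliage-associated substrate (phloem) C
I_NLE = 5       # foliage-associated substrate (phloem) N
I_CLIT = 6      # surface litter C
I_NLIT = 7      # surface litter N
I_CSOIL = 8     # soil organic C
I_NSOIL = 9     # soil organic N
I_NMIN = 10     # soil mineral N

# aphid stages (aphids per stem): apterous instars 1-4, apterous adult,
# alate instars 1-4, alate adult
I_APH = 11
N_APH = 10
I_AP_ADULT = I_APH + 4
I_AL_ADULT = I_APH + 9

# cumulative boundary fluxes (kg m-2)
I_CUM_PHOTO = 21      # gross canopy photosynthesis (C in)
I_CUM_RPLANT = 22     # plant growth + maintenance respiration (C out)
I_CUM_RSOIL = 23      # litter + soil heterotrophic respiration (C out)
I_CUM_ARESP = 24      # aphid respiration (C out)
I_CUM_HARV_C = 25     # stem-wood C removed at thinnings/clear-fell (C out)
I_CUM_HARV_N = 26     # stem-wood N removed (N out)
I_CUM_EMIG_C = 27     # net alate migration export (C out; emigration - immigration)
I_CUM_EMIG_N = 28     # net alate migration export (N out)
I_CUM_NDEP = 29       # atmospheric N deposition (N in)
I_CUM_NLEACH = 30     # mineral-N leaching (N out)

N_STATE = 31

APHID_STAGE_NAMES = (
    "ap_i1", "ap_i2", "ap_i3", "ap_i4", "ap_adult",
    "al_i1", "al_i2", "al_i3", "al_i4", "al_adult",
)
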