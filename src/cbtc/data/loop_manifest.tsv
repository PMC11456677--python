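# Default CBTC loop manifest (reconstruction by rule; see docs/methods.md).
# Per hemisphere: 19 short-loop, 21 long-loop, 26 atlas edges.
loop	hemisphere	region_a	region_b
short	L	MPFC	CAU_MPFC
short	L	CAU_MPFC	THA_MPFC
short	L	MPFC	THA_MPFC
short	L	DLPFC	CAU_DLPFC
short	L	DLPFC	PUT_DLPFC
short	L	CAU_DLPFC	THA_DLPFC
short	L	PUT_DLPFC	THA_DLPFC
short	L	DLPFC	THA_DLPFC
short	L	M1	CAU_M1
short	L	M1	PUT_M1
short	L	CAU_M1	THA_M1
short	L	PUT_M1	THA_M1
short	L	M1	THA_M1
short	L	PMC	CAU_PMC
short	L	PMC	PUT_PMC
short	L	CAU_PMC	THA_PMC
short	L	PUT_PMC	THA_PMC
short	L	PMC	THA_PMC
short	L	OFC	CAU_OFC
long	L	MPFC	CAU_MPFC
long	L	CAU_MPFC	PAL_MPFC
long	L	DLPFC	CAU_DLPFC
long	L	DLPFC	PUT_DLPFC
long	L	CAU_DLPFC	PAL_DLPFC
long	L	PUT_DLPFC	PAL_DLPFC
long	L	PAL_DLPFC	THA_DLPFC
long	L	DLPFC	THA_DLPFC
long	L	M1	CAU_M1
long	L	M1	PUT_M1
long	L	CAU_M1	PAL_M1
long	L	PUT_M1	PAL_M1
long	L	PAL_M1	THA_M1
long	L	M1	THA_M1
long	L	PMC	CAU_PMC
long	L	PMC	PUT_PMC
long	L	CAU_PMC	PAL_PMC
long	L	PUT_PMC	PAL_PMC
long	L	PAL_PMC	THA_PMC
long	L	PMC	THA_PMC
long	L	OFC	CAU_OFC
atlas	L	MPFC	CAU
atlas	L	MPFC	PUT
atlas	L	MPFC	PAL
atlas	L	MPFC	THA
atlas	L	DLPFC	CAU
atlas	L	DLPFC	PUT
atlas	L	DLPFC	PAL
atlas	L	DLPFC	THA
atlas	L	M1	CAU
atlas	L	M1	PUT
atlas	L	M1	PAL
atlas	L	M1	THA
atlas	L	PMC	CAU
atlas	L	PMC	PUT
atlas	L	PMC	PAL
atlas	L	PMC	THA
atlas	L	OFC	CAU
atlas	L	OFC	PUT
atlas	L	OFC	PAL
atlas	L	OFC	THA
atlas	L	CAU	PUT
atlas	L	CAU	PAL
atlas	L	CAU	THA
atlas	L	PUT	PAL
atlas	L	PUT	THA
atlas	L	PAL	THA
short	R	MPFC	CAU_MPFC
short	R	CAU_MPFC	THA_MPFC
short	R	MPFC	THA_MPFC
short	R	DLPFC	CAU_DLPFC
short	R	DLPFC	PUT_DLPFC
short	R	CAU_DLPFC	THA_DLPFC
short	R	PUT_DLPFC	THA_DLPFC
short	R	DLPFC	THA_DLPFC
short	R	M1	CAU_M1
short	R	M1	PUT_M1
short	R	CAU_M1	THA_M1
short	R	PUT_M1	THA_M1
short	R	M1	THA_M1
short	R	PMC	CAU_PMC
short	R	PMC	PUT_PMC
short	R	CAU_PMC	THA_PMC
short	R	PUT_PMC	THA_PMC
short	R	PMC	THA_PMC
short	R	OFC	CAU_OFC
long	R	MPFC	CAU_MPFC
long	R	CAU_MPFC	PAL_MPFC
long	R	DLPFC	CAU_DLPFC
long	R	DLPFC	PUT_DLPFC
long	R	CAU_DLPFC	PAL_DLPFC
long	R	PUT_DLPFC	PAL_DLPFC
long	R	PAL_DLPFC	THA_DLPFC
long	R	DLPFC	THA_DLPFC
long	R	M1	CAU_M1
long	R	M1	PUT_M1
long	R	CAU_M1	PAL_M1
long	R	PUT_M1	PAL_M1
long	R	PAL_M1	THA_M1
long	R	M1	THA_M1
long	R	PMC	CAU_PMC
long	R	PMC	PUT_PMC
long	R	CAU_PMC	PAL_PMC
long	R	PUT_PMC	PAL_PMC
long	R	PAL_PMC	THA_PMC
long	R	PMC	THA_PMC
long	R	OFC	CAU_OFC
atlas	R	MPFC	CAU
atlas	R	MPFC	PUT
atlas	R	MPFC	PAL
atlas	R	MPFC	THA
atlas	R	DLPFC	CAU
atlas	R	DLPFC	PUT
atlas	R	DLPFC	PAL
atlas	R	DLPFC	THA
atlas	R	M1	CAU
atlas	R	M1	PUT
atlas	R	M1	PAL
atlas	R	M1	THA
atlas	R	PMC	CAU
atlas	R	PMC	PUT
atlas	R	PMC	PAL
atlas	R	PMC	THA
atlas	R	OFC	CAU
atlas	R	OFC	PUT
atlas	R	OFC	PAL
atlas	R	OFC	THA
atlas	R	CAU	PUT
atlas	R	CAU	PAL
atlas	R	CAU	THA
atlas	R	PUT	PAL
atlas	R	PUT	THA
atlas	R	PAL	THA
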