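# pBTR destination-vector registry.
# name	set	category	plant_marker	fwd_adapter	rev_adapter
# Adapter patterns are the constant primer 5' tails; N placeholders are
# concretized at design time.  Vector overhangs are derived as the reverse
# complements of each adapter's 3'-terminal 4-mer.
pH35BTR1	BTR1	overexpression_35S	HygR	NNNNGGTCTCNGATG	NNNNGGTCTCNATCC
pK35BTR1	BTR1	overexpression_35S	KanR	NNNNGGTCTCNGATG	NNNNGGTCTCNATCC
pR35BTR1	BTR1	overexpression_35S	DsRed	NNNNGGTCTCNGATG	NNNNGGTCTCNATCC
pH35BTR2	BTR2	overexpression_35S	HygR	NNNNGGTCTCNTAGA	NNNNGGTCTCNGCTC
pK35BTR2	BTR2	overexpression_35S	KanR	NNNNGGTCTCNTAGA	NNNNGGTCTCNGCTC
pR35BTR2	BTR2	overexpression_35S	DsRed	NNNNGGTCTCNTAGA	NNNNGGTCTCNGCTC
pBUbiBTR1	BTR1	overexpression_Ubi	BarR	NNNNGGTCTCNGATG	NNNNGGTCTCNATCC
pHUbiBTR1	BTR1	overexpression_Ubi	HygR	NNNNGGTCTCNGATG	NNNNGGTCTCNATCC
pKUbiBTR1	BTR1	overexpression_Ubi	KanR	NNNNGGTCTCNGATG	NNNNGGTCTCNATCC
pBUbiBTR2	BTR2	overexpression_Ubi	BarR	NNNNGGTCTCNCAGA	NNNNGGTCTCNGCTC
pHUbiBTR2	BTR2	overexpression_Ubi	HygR	NNNNGGTCTCNCAGA	NNNNGGTCTCNGCTC
pKUbiBTR2	BTR2	overexpression_Ubi	KanR	NNNNGGTCTCNCAGA	NNNNGGTCTCNGCTC
pHNatBTR1	BTR1	native_promoter	HygR	NNNNGGTCTCNGCTT	NNNNGGTCTCNATCC
pKNatBTR1	BTR1	native_promoter	KanR	NNNNGGTCTCNGCTT	NNNNGGTCTCNATCC
pRNatBTR1	BTR1	native_promoter	DsRed	NNNNGGTCTCNGCTT	NNNNGGTCTCNATCC
pHNatBTR2	BTR2	native_promoter	HygR	NNNNGGTCTCNCTTT	NNNNGGTCTCNTCCT
pKNatBTR2	BTR2	native_promoter	KanR	NNNNGGTCTCNCTTT	NNNNGGTCTCNTCCT
pRNatBTR2	BTR2	native_promoter	DsRed	NNNNGGTCTCNCTTT	NNNNGGTCTCNTCCT
pHBTR1PGUS	BTR1	promoter_GUS	HygR	NNNNGGTCTCNGCTT	NNNNGGTCTCNATCT
pKBTR1PGUS	BTR1	promoter_GUS	KanR	NNNNGGTCTCNGCTT	NNNNGGTCTCNATCT
pRBTR1PGUS	BTR1	promoter_GUS	DsRed	NNNNGGTCTCNGCTT	NNNNGGTCTCNATCT
pHBTR2PGUS	BTR2	promoter_GUS	HygR	NNNNGGTCTCNCTTT	NNNNGGTCTCNAGAA
pKBTR2PGUS	BTR2	promoter_GUS	KanR	NNNNGGTCTCNCTTT	NNNNGGTCTCNAGAA
pRBTR2PGUS	BTR2	promoter_GUS	DsRed	NNNNGGTCTCNCTTT	NNNNGGTCTCNAGAA
pK35BTR1GFP	BTR1	subcellular_GFP	KanR	NNNNGGTCTCNGATG	NNNNGGTCTCNCTCC
pK35BTR2GFP	BTR2	subcellular_GFP	KanR	NNNNGGTCTCNTAGA	NNNNGGTCTCNCACC
pSHBTR1	BTR1	empty_SBTR	HygR	NNNNGGTCTCNGATG	NNNNGGTCTCNATCC
pSKBTR1	BTR1	empty_SBTR	KanR	NNNNGGTCTCNGATG	NNNNGGTCTCNATCC
pSRBTR1	BTR1	empty_SBTR	DsRed	NNNNGGTCTCNGATG	NNNNGGTCTCNATCC
pSHBTR2	BTR2	empty_SBTR	HygR	NNNNGGTCTCNTAGA	NNNNGGTCTCNGCTC
pSKBTR2	BTR2	empty_SBTR	KanR	NNNNGGTCTCNTAGA	NNNNGGTCTCNGCTC
pSRBTR2	BTR2	empty_SBTR	DsRed	NNNNGGTCTCNTAGA	NNNNGGTCTCNGCTC
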