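individual_id	cohort	gene	variant_id	maf	domain
DR554.1	patient	FLNC	p.R81C		CH1
DR1221.1	patient	FLNC	p.E309K		Ig 1
DR1222.1	patient	FLNC	p.E323V		Ig 1
DR659.1	patient	FLNC	p.K524R		Ig 3
DR454.1	patient	FLNC	p.D710N		Ig 5
DR1223.1	patient	FLNC	p.A806T		Ig 6
ADR1	patient	FLNC	p.V831I		Ig 6
DR1224.1	patient	FLNC	p.V1047L		Ig 8
AD1485.1	patient	FLNC	p.P1163R		Ig 10
AD1430.1	patient	FLNC	p.V1335M		Ig 11
DR1225.1	patient	FLNC	p.L1364F		Ig 12
AD1788.1	patient	FLNC	p.R1370Q		Ig 12
DR867.1	patient	FLNC	p.A1551T		Ig 14
DR559.1	patient	FLNC	p.E1571K		Ig 14
DR1226.1	patient	FLNC	p.E1571K		Ig 14
DR355.1	patient	FLNC	p.R1758W		Linker Ig 15-16
DR825.1	patient	FLNC	p.V2014A		Ig 18
AD1462.1	patient	FLNC	p.T2025I		Ig 18
DR1227.1	patient	FLNC	p.T2025I		Ig 18
DR868.1	patient	FLNC	p.R2318Q		Ig 21
AD1321.1	patient	FLNC	p.S2461N		Ig 22
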