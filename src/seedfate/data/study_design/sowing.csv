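station_id,microhabitat,zone,set_id,treatment,n_sown,n_emerged,n_surviving
ST001,OPEN,A,SA1,DIGESTED,10,7,0
ST001,OPEN,A,SA1,RED,10,5,0
ST001,OPEN,A,SA1,YELLOW,10,5,1
ST002,OPEN,A,SA2,DIGESTED,10,1,0
ST002,OPEN,A,SA2,RED,10,4,0
ST002,OPEN,A,SA2,YELLOW,10,1,0
ST003,OPEN,A,SA3,DIGESTED,10,6,0
ST003,OPEN,A,SA3,RED,10,0,0
ST003,OPEN,A,SA3,YELLOW,10,2,0
ST004,OPEN,A,SA4,DIGESTED,10,5,0
ST004,OPEN,A,SA4,RED,10,5,0
ST004,OPEN,A,SA4,YELLOW,10,4,0
ST005,OPEN,A,SA5,DIGESTED,10,4,0
ST005,OPEN,A,SA5,RED,10,7,0
ST005,OPEN,A,SA5,YELLOW,10,1,0
ST006,OPEN,A,SA6,DIGESTED,10,5,2
ST006,OPEN,A,SA6,RED,10,3,0
ST006,OPEN,A,SA6,YELLOW,10,2,0
ST007,OPEN,A,SA7,DIGESTED,10,2,0
ST007,OPEN,A,SA7,RED,10,3,0
ST007,OPEN,A,SA7,YELLOW,10,1,0
ST008,OPEN,A,SA8,DIGESTED,10,5,0
ST008,OPEN,A,SA8,RED,10,6,2
ST008,OPEN,A,SA8,YELLOW,10,4,0
ST009,OPEN,A,SA9,DIGESTED,10,6,1
ST009,OPEN,A,SA9,RED,10,3,0
ST009,OPEN,A,SA9,YELLOW,10,0,0
ST010,OPEN,A,SA10,DIGESTED,10,5,1
ST010,OPEN,A,SA10,RED,10,8,1
ST010,OPEN,A,SA10,YELLOW,10,4,0
ST011,EPHEDRA,A,SA1,DIGESTED,10,2,0
ST011,EPHEDRA,A,SA1,RED,10,0,0
ST011,EPHEDRA,A,SA1,YELLOW,10,2,0
ST012,EPHEDRA,A,SA2,DIGESTED,10,1,0
ST012,EPHEDRA,A,SA2,RED,10,0,0
ST012,EPHEDRA,A,SA2,YELLOW,10,0,0
ST013,EPHEDRA,A,SA3,DIGESTED,10,2,0
ST013,EPHEDRA,A,SA3,RED,10,1,0
ST013,EPHEDRA,A,SA3,YELLOW,10,0,0
ST014,EPHEDRA,A,SA4,DIGESTED,10,4,0
ST014,EPHEDRA,A,SA4,RED,10,2,0
ST014,EPHEDRA,A,SA4,YELLOW,10,1,0
ST015,EPHEDRA,A,SA5,DIGESTED,10,0,0
ST015,EPHEDRA,A,SA5,RED,10,0,0
ST015,EPHEDRA,A,SA5,YELLOW,10,1,0
ST016,EPHEDRA,A,SA6,DIGESTED,10,1,0
ST016,EPHEDRA,A,SA6,RED,10,2,0
ST016,EPHEDRA,A,SA6,YELLOW,10,0,0
ST017,EPHEDRA,A,SA7,DIGESTED,10,0,0
ST017,EPHEDRA,A,SA7,RED,10,1,0
ST017,EPHEDRA,A,SA7,YELLOW,10,2,0
ST018,EPHEDRA,A,SA8,DIGESTED,10,0,0
ST018,EPHEDRA,A,SA8,RED,10,1,0
ST018,EPHEDRA,A,SA8,YELLOW,10,2,0
ST019,EPHEDRA,A,SA9,DIGESTED,10,1,0
ST019,EPHEDRA,A,SA9,RED,10,3,0
ST019,EPHEDRA,A,SA9,YELLOW,10,1,0
ST020,EPHEDRA,A,SA10,DIGESTED,10,0,0
ST020,EPHEDRA,A,SA10,RED,10,0,0
ST020,EPHEDRA,A,SA10,YELLOW,10,0,0
ST021,PISTACIA,A,SA1,DIGESTED,10,6,1
ST021,PISTACIA,A,SA1,RED,10,1,0
ST021,PISTACIA,A,SA1,YELLOW,10,4,0
ST022,PISTACIA,A,SA2,DIGESTED,10,3,0
ST022,PISTACIA,A,SA2,RED,10,3,2
ST022,PISTACIA,A,SA2,YELLOW,10,5,0
ST023,PISTACIA,A,SA3,DIGESTED,10,7,1
ST023,PISTACIA,A,SA3,RED,10,6,0
ST023,PISTACIA,A,SA3,YELLOW,10,1,0
ST024,PISTACIA,A,SA4,DIGESTED,10,3,1
ST024,PISTACIA,A,SA4,RED,10,6,2
ST024,PISTACIA,A,SA4,YELLOW,10,2,0
ST025,PISTACIA,A,SA5,DIGESTED,10,5,0
ST025,PISTACIA,A,SA5,RED,10,2,0
ST025,PISTACIA,A,SA5,YELLOW,10,5,1
ST026,PISTACIA,A,SA6,DIGESTED,10,3,0
ST026,PISTACIA,A,SA6,RED,10,4,1
ST026,PISTACIA,A,SA6,YELLOW,10,4,0
ST027,PISTACIA,A,SA7,DIGESTED,10,2,0
ST027,PISTACIA,A,SA7,RED,10,3,0
ST027,PISTACIA,A,SA7,YELLOW,10,3,0
ST028,PISTACIA,A,SA8,DIGESTED,10,2,0
ST028,PISTACIA,A,SA8,RED,10,0,0
ST028,PISTACIA,A,SA8,YELLOW,10,0,0
ST029,PISTACIA,A,SA9,DIGESTED,10,2,0
ST029,PISTACIA,A,SA9,RED,10,1,0
ST029,PISTACIA,A,SA9,YELLOW,10,2,0
ST030,PISTACIA,A,SA10,DIGESTED,10,4,0
ST030,PISTACIA,A,SA10,RED,10,4,0
ST030,PISTACIA,A,SA10,YELLOW,10,1,0
ST031,OPEN,B,SB1,DIGESTED,10,1,0
ST031,OPEN,B,SB1,RED,10,3,0
ST031,OPEN,B,SB1,YELLOW,10,2,0
ST032,OPEN,B,SB2,DIGESTED,10,6,1
ST032,OPEN,B,SB2,RED,10,4,0
ST032,OPEN,B,SB2,YELLOW,10,2,0
ST033,OPEN,B,SB3,DIGESTED,10,6,1
ST033,OPEN,B,SB3,RED,10,4,1
ST033,OPEN,B,SB3,YELLOW,10,3,0
ST034,OPEN,B,SB4,DIGESTED,10,8,1
ST034,OPEN,B,SB4,RED,10,5,0
ST034,OPEN,B,SB4,YELLOW,10,4,1
ST035,OPEN,B,SB5,DIGESTED,10,6,1
ST035,OPEN,B,SB5,RED,10,5,0
ST035,OPEN,B,SB5,YELLOW,10,5,2
ST036,OPEN,B,SB6,DIGESTED,10,5,0
ST036,OPEN,B,SB6,RED,10,7,0
ST036,OPEN,B,SB6,YELLOW,10,3,0
ST037,OPEN,B,SB7,DIGESTED,10,8,3
ST037,OPEN,B,SB7,RED,10,5,0
ST037,OPEN,B,SB7,YELLOW,10,2,0
ST038,OPEN,B,SB8,DIGESTED,10,7,1
ST038,OPEN,B,SB8,RED,10,3,0
ST038,OPEN,B,SB8,YELLOW,10,2,0
ST039,OPEN,B,SB9,DIGESTED,10,2,0
ST039,OPEN,B,SB9,RED,10,5,0
ST039,OPEN,B,SB9,YELLOW,10,0,0
ST040,OPEN,B,SB10,DIGESTED,10,3,1
ST040,OPEN,B,SB10,RED,10,4,0
ST040,OPEN,B,SB10,YELLOW,10,3,0
ST041,EPHEDRA,B,SB1,DIGESTED,10,0,0
ST041,EPHEDRA,B,SB1,RED,10,1,0
ST041,EPHEDRA,B,SB1,YELLOW,10,3,0
ST042,EPHEDRA,B,SB2,DIGESTED,10,1,0
ST042,EPHEDRA,B,SB2,RED,10,0,0
ST042,EPHEDRA,B,SB2,YELLOW,10,0,0
ST043,EPHEDRA,B,SB3,DIGESTED,10,2,0
ST043,EPHEDRA,B,SB3,RED,10,1,0
ST043,EPHEDRA,B,SB3,YELLOW,10,0,0
ST044,EPHEDRA,B,SB4,DIGESTED,10,0,0
ST044,EPHEDRA,B,SB4,RED,10,4,0
ST044,EPHEDRA,B,SB4,YELLOW,10,0,0
ST045,EPHEDRA,B,SB5,DIGESTED,10,0,0
ST045,EPHEDRA,B,SB5,RED,10,0,0
ST045,EPHEDRA,B,SB5,YELLOW,10,0,0
ST046,EPHEDRA,B,SB6,DIGESTED,10,0,0
ST046,EPHEDRA,B,SB6,RED,10,0,0
ST046,EPHEDRA,B,SB6,YELLOW,10,0,0
ST047,EPHEDRA,B,SB7,DIGESTED,10,0,0
ST047,EPHEDRA,B,SB7,RED,10,1,0
ST047,EPHEDRA,B,SB7,YELLOW,10,0,0
ST048,EPHEDRA,B,SB8,DIGESTED,10,1,0
ST048,EPHEDRA,B,SB8,RED,10,3,0
ST048,EPHEDRA,B,SB8,YELLOW,10,1,0
ST049,EPHEDRA,B,SB9,DIGESTED,10,3,0
ST049,EPHEDRA,B,SB9,RED,10,1,0
ST049,EPHEDRA,B,SB9,YELLOW,10,0,0
ST050,EPHEDRA,B,SB10,DIGESTED,10,0,0
ST050,EPHEDRA,B,SB10,RED,10,1,0
ST050,EPHEDRA,B,SB10,YELLOW,10,0,0
ST051,PISTACIA,B,SB1,DIGESTED,10,4,1
ST051,PISTACIA,B,SB1,RED,10,5,0
ST051,PISTACIA,B,SB1,YELLOW,10,6,0
ST052,PISTACIA,B,SB2,DIGESTED,10,1,0
ST052,PISTACIA,B,SB2,RED,10,4,0
ST052,PISTACIA,B,SB2,YELLOW,10,1,0
ST053,PISTACIA,B,SB3,DIGESTED,10,1,0
ST053,PISTACIA,B,SB3,RED,10,4,1
ST053,PISTACIA,B,SB3,YELLOW,10,0,0
ST054,PISTACIA,B,SB4,DIGESTED,10,5,1
ST054,PISTACIA,B,SB4,RED,10,4,0
ST054,PISTACIA,B,SB4,YELLOW,10,4,0
ST055,PISTACIA,B,SB5,DIGESTED,10,2,0
ST055,PISTACIA,B,SB5,RED,10,2,1
ST055,PISTACIA,B,SB5,YELLOW,10,2,0
ST056,PISTACIA,B,SB6,DIGESTED,10,5,0
ST056,PISTACIA,B,SB6,RED,10,6,0
ST056,PISTACIA,B,SB6,YELLOW,10,1,0
ST057,PISTACIA,B,SB7,DIGESTED,10,0,0
ST057,PISTACIA,B,SB7,RED,10,8,0
ST057,PISTACIA,B,SB7,YELLOW,10,0,0
ST058,PISTACIA,B,SB8,DIGESTED,10,3,0
ST058,PISTACIA,B,SB8,RED,10,1,0
ST058,PISTACIA,B,SB8,YELLOW,10,5,1
ST059,PISTACIA,B,SB9,DIGESTED,10,3,0
ST059,PISTACIA,B,SB9,RED,10,3,0
ST059,PISTACIA,B,SB9,YELLOW,10,2,0
ST060,PISTACIA,B,SB10,DIGESTED,10,4,0
ST060,PISTACIA,B,SB10,RED,10,4,1
ST060,PISTACIA,B,SB10,YELLOW,10,3,1
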