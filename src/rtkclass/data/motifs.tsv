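name	rtk_class	subtype	region	consensus	bold_positions	source
InsR1_FN3	InsR	InsR1	fn3	RYAVYVETDTVADADIGARS	2,3,6,20	decapod-rtk-consensus-v1
InsR2_FN3	InsR	InsR2	fn3	RYAVxVKxxSLxSSxxGAQS	2,3,6,20	decapod-rtk-consensus-v1
InsR3_FN3	InsR	InsR3	fn3	xYAxYVxxYYTDxxKxxSRS	2,3,6,20	decapod-rtk-consensus-v1
InsR_catalytic	InsR		catalytic	VHRDLAARNC	1,2,3,4,5,6,7,8,9,10	decapod-rtk-consensus-v1
FGFR1_catalytic	FGFR	FGFR1	catalytic	VAVKMLKEGHTDxELMDLVSEMEMMKMIGTHINIINLLGCCTQDGPLYVVVEYAAHGNLRDYLRNxRxxSGYERxIGQExxxxxxxDLVSFxxQVARGMEYLxSxKCIHRDLAARNVL	1,2,3,4,7,14,17,18,21,29,33,38,40,41,42,43,44,45,46,52,53,57,59,63,64,67,72,87,88,94,98,109,110,111,112,113,115,116,118	decapod-rtk-consensus-v1
FGFR2_catalytic	FGFR	FGFR2	catalytic	VAVKTxKESAxxRERxDLVQELKVLKxLGxHxNVxSxLxCCxxKxPxFxxLEYMxxGKLQSxLRxSRADTxYxN-LHGSSSSxTPxDLxxxxYQxxRGMEFLxRNxxxHRDLAxRNxL	1,2,3,4,7,14,17,18,21,29,33,38,40,41,46,52,53,57,59,63,64,67,72,87,88,94,98,109,110,111,112,113,115,116,118	decapod-rtk-consensus-v1
FGFR3_catalytic	FGFR	FGFR3	catalytic	VAVKGVKxGAGxKEKQDLLxELxIMQHxGxxxNVVTLLGCCTQQEPxxVIMEYVMFGKLLxFLRDHRTRxNYYN-FSSDTxALTSxDLTRFACQVAxGCEYxQSRGIIHRDLAxRNxL	1,2,3,4,7,14,17,18,21,29,33,38,40,41,46,52,53,57,59,63,64,67,72,87,88,94,98,109,110,111,112,113,115,116,118	decapod-rtk-consensus-v1
PVR1_catalytic	PVR	PVR1	catalytic	YQIAKGMEYLAFKKVLHGDLAARNVLLxxNNVVKISDFGLAKDIYxNxNYKKxxxGPVPVKW	2,4,6,7,9,10,17,18,19,20,21,23,24,26,27,31,34,35,36,37,38,39,45,50,52,59,61,62	decapod-rtk-consensus-v1
PVR2A_catalytic	PVR	PVR2A	catalytic	WQxAxGMxYLSRRxxLHGDLAARNLLLxDNNVxKISDFGxSRxxYxxxxYxKxxDxxxPxKW	2,4,6,7,9,10,17,18,19,20,21,23,24,26,27,31,34,35,36,37,38,39,45,50,52,59,61,62	decapod-rtk-consensus-v1
PVR2B_catalytic	PVR	PVR2B	catalytic	WQVAxGMxYLxxRKVLHGDLAARNLLLxDDNxxKISDFGLSRxMYKKDxYMKKxDDLMPIKW	2,4,6,7,9,10,17,18,19,20,21,23,24,26,27,31,34,35,36,37,38,39,45,50,52,59,61,62	decapod-rtk-consensus-v1
EGFR1_catalytic	EGFR	EGFR1	catalytic	TRSMSYLEDKQLVGHRDLASRNVLLTNGHQVQVSENGLARLIEDSEYTAKQGAKYGERWLALESLADNVYTTHSDVWAFG	15,16,17,18,19	artifact-egfr-fixture-v1
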