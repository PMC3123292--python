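<ROSETTASCRIPTS>
	<SCOREFXNS>
		<myscore weights = enzdes.wts/> Read the enzdes.wts score function from the database
	</SCOREFXNS>
	<FILTERS>
		<EnzScore name="allcst" score_type = cstE scorefxn = myscore whole_pose = 1 energy_cutoff = 5/> filter on the constraint scores
		<LigInterfaceEnergy name="interfE" scorefxn = myscore energy_cutoff = -9.0/> filter on the energy across the interface
		<CompoundStatement name="myfilter">
			<AND filter_name="allcst"/>
			<AND filter_name="interfE"/>
		</CompoundStatement>
	</FILTERS>
	<MOVERS>
		<AddOrRemoveMatchCsts name = cstadd cst_instruction = add_new/> add catalytic constraints
		<EnzRepackMinimize name = cstopt cst_opt = 1 minimize_rb = 1 minimize_sc = 1 minimize_bb = 1/> optimize constraints energy in polyAla background
		<EnzRepackMinimize name = desmin design = 1 repack_only = 0 scorefxn_minimize = myscore scorefxn_repack = myscore minimize_rb = 1 minimize_sc = 1 minimize_bb = 1 cycles = 1/>
		<EnzRepackMinimize name = fin_min repack_only = 0 design = 0 scorefxn_minimize = myscore scorefxn_repack = myscore minimize_rb = 1 minimize_sc = 1 minimize_bb = 1 cycles = 1/>
		<EnzRepackMinimize name = fin_rpkmin repack_only = 1 design = 0 scorefxn_minimize = myscore scorefxn_repack = myscore minimize_rb = 1 minimize_sc = 1 minimize_bb = 1 cycles = 1/>
		<AddOrRemoveMatchCsts name = cstrem cst_instruction = remove keep_covalent = 1/> remove constraints
		<AddOrRemoveMatchCsts name = cstfinadd cst_instruction = add_pregenerated/> add the last set of constraints added just prior to removing them (used for scoring typically at the end of the trajectory)
	</MOVERS>
	<PROTOCOLS>
		<Add mover_name = cstadd/>
		<Add mover_name = cstopt/>
		<Add mover_name = desmin/>
		<Add mover_name = cstrem/>
		<Add mover_name = fin_min/>
		<Add mover_name = fin_rpkmin/>
		<Add mover_name = cstfinadd/>
	</PROTOCOLS>
</ROSETTASCRIPTS>
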